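"""qPCR relative expression (2^-ddCt) and AOI probe filtering/normalization.

The AOI path implements negative-probe limits of quantification (geometric
mean × squared geometric SD, i.e. two log-space SDs above the geometric
mean), prevalence-based gene filtering, and third-quartile normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gliamap.transcriptomics import de_wilcoxon  # noqa: F401  (re-exported path)
import anndata as ad

NEGPROBE_PREFIX = "NegProbe"
DEFAULT_KEEP_FRACTION = 0.15


@dataclass
class LOQParams:
    n_sd: float = 2.0
    keep_fraction: float = DEFAULT_KEEP_FRACTION
    log_space: bool = True   # geometric (log2-space) SD; False = plain scale

    def validate(self) -> None:
        if not (0 < self.keep_fraction <= 1):
            raise ValueError("keep_fraction must be in (0, 1]")
        if self.n_sd <= 0:
            raise ValueError("n_sd must be > 0")


def ddct(
    ct: pd.DataFrame,
    housekeeper: str = "Hprt",
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Relative expression via the 2^-ddCt method.

    ``ct`` is long-form with columns sample, group, gene, Ct and optionally
    sex/tissue. Each sample must include the housekeeper. dCt is referenced
    to the mean dCt of the reference group — per sex when a sex column is
    present. Rows with missing Ct are dropped and reported via attrs.
    """
    required = {"sample", "group", "gene", "Ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"ct table needs columns {sorted(required)}")
    if reference_group is None:
        raise ValueError("reference_group is required")
    df = ct.copy()
    dropped = df[df["Ct"].isna()]
    df = df.dropna(subset=["Ct"])
    hk = df[df["gene"] == housekeeper].set_index("sample")["Ct"]
    targets = df[df["gene"] != housekeeper].copy()
    missing_hk = sorted(set(targets["sample"]) - set(hk.index))
    if missing_hk:
        raise ValueError(f"housekeeper {housekeeper} missing for samples: {missing_hk}")
    targets["dCt"] = targets["Ct"].to_numpy() - hk.loc[targets["sample"]].to_numpy()
    if reference_group not in set(targets["group"]):
        raise ValueError(f"reference group empty: {reference_group}")

    strata = ["gene", "sex"] if "sex" in targets.columns else ["gene"]
    ref = (
        targets[targets["group"] == reference_group]
        .groupby(strata, observed=True)["dCt"].mean()
        .rename("ref_dCt")
    )
    targets = targets.merge(ref, on=strata, how="left")
    if targets["ref_dCt"].isna().any():
        bad = targets.loc[targets["ref_dCt"].isna(), strata].drop_duplicates()
        raise ValueError(f"no reference values for strata:\n{bad}")
    targets["ddCt"] = targets["dCt"] - targets["ref_dCt"]
    targets["relative_expression"] = 2.0 ** (-targets["ddCt"])
    targets.attrs["n_dropped_missing_ct"] = int(len(dropped))
    return targets


def split_negprobes(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a genes × AOIs table into (gene rows, negative-probe rows)."""
    is_neg = counts.index.str.startswith(NEGPROBE_PREFIX)
    return counts.loc[~is_neg], counts.loc[is_neg]


def loq_per_aoi(neg: pd.DataFrame, params: LOQParams | None = None) -> pd.Series:
    """Per-AOI limit of quantification from negative-probe counts.

    Log-space rule: LOQ = 2^(mean(log2 neg) + n_sd · sd(log2 neg)), i.e. the
    geometric mean times geometric SD^n_sd. Needs ≥2 negative probes per AOI.
    """
    params = params or LOQParams()
    params.validate()
    if neg.shape[0] < 2:
        raise ValueError("need >= 2 negative probes per AOI")
    if params.log_space:
        logs = np.log2(neg.astype(float).clip(lower=0.5))
        return (2.0 ** (logs.mean(axis=0) + params.n_sd * logs.std(axis=0, ddof=1))
                ).rename("loq")
    m, s = neg.mean(axis=0), neg.std(axis=0, ddof=1)
    return (m + params.n_sd * s).rename("loq")


def loq_filter(
    counts: pd.DataFrame, params: LOQParams | None = None
) -> tuple[list[str], pd.Series, pd.DataFrame]:
    """Keep genes detected above the per-AOI LOQ in ≥ keep_fraction of AOIs.

    The prevalence boundary is inclusive: exactly 15% of AOIs above LOQ keeps
    a gene at the default fraction. Returns (kept genes, per-AOI LOQ, report
    table with per-gene prevalence).
    """
    params = params or LOQParams()
    genes, neg = split_negprobes(counts)
    if neg.empty:
        raise ValueError("no negative-probe rows in counts table")
    loq = loq_per_aoi(neg, params)
    above = genes.gt(loq, axis=1)
    prevalence = above.mean(axis=1)
    kept = prevalence[prevalence >= params.keep_fraction].index.tolist()
    report = pd.DataFrame({
        "gene": genes.index,
        "n_above_loq": above.sum(axis=1).to_numpy(),
        "prevalence": prevalence.to_numpy(),
        "kept": [g in set(kept) for g in genes.index],
    })
    return kept, loq, report


def q3_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Third-quartile normalization across AOIs (columns).

    factor_a = Q3 of AOI a over the kept genes; every AOI is rescaled by
    geomean(factors)/factor_a so post-normalization Q3s are all equal.
    """
    if counts.shape[0] < 4:
        raise ValueError("need >= 4 kept genes per AOI")
    q3 = counts.quantile(0.75, axis=0)
    if (q3 <= 0).any():
        bad = q3[q3 <= 0].index.tolist()
        raise ValueError(f"zero third quartile for AOI(s): {bad}")
    geo = float(np.exp(np.log(q3).mean()))
    return counts * (geo / q3)


def aoi_de(
    normalized: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> pd.DataFrame:
    """Differential expression between two AOI sets (rank-sum + BH).

    Delegates to the single-cell rank-sum machinery: AOIs play the role of
    cells (genes × AOIs input is transposed internally).
    """
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    cols = list(group_a) + list(group_b)
    missing = [c for c in cols if c not in normalized.columns]
    if missing:
        raise ValueError(f"unknown AOI(s): {missing}")
    mat = normalized[cols].T
    adata = ad.AnnData(
        X=mat.to_numpy(dtype=float),
        obs=pd.DataFrame(index=mat.index),
        var=pd.DataFrame(index=mat.columns),
    )
    mask_a = np.isin(mat.index, list(group_a))
    return de_wilcoxon(adata, mask_a, ~mask_a, layer="X")


__all__ = [
    "LOQParams", "ddct", "split_negprobes", "loq_per_aoi", "loq_filter",
    "q3_normalize", "aoi_de", "NEGPROBE_PREFIX",
]
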