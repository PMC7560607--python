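"""Label-free spectral-count enrichment analysis (NSAF pipeline).

Compares sorted mossy-fiber (MF) synaptosomes against the crude P2
synaptosome reference using normalized spectral abundance factors:

    NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j)      per sample,

where SpC is a protein's spectral count and L its length in amino acids.
The pipeline is: summed-peptide detection filter -> NSAF -> zero imputation
for undetected proteins -> log2 fold change of group means -> per-protein
two-sample t test -> Benjamini-Hochberg q-values with a 5%-FDR
high-confidence cutoff -> detection-class report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GROUP_MF = "MF"
GROUP_P2 = "P2"

CLASS_SHARED = "shared"
CLASS_MF_EXCLUSIVE = "MF-exclusive"
CLASS_P2_EXCLUSIVE = "P2-exclusive"
CLASS_UNDETECTED = "undetected-after-filter"

__all__ = [
    "spc_columns", "pep_columns", "read_counts_tsv",
    "filter_by_peptides", "compute_nsaf", "impute_missing",
    "log2_fold_change", "protein_t_test", "bh_adjust",
    "classify_and_report", "run_enrichment", "EnrichmentSummary",
]


def spc_columns(table: pd.DataFrame, group: str | None = None) -> list[str]:
    cols = [c for c in table.columns if c.startswith("spc_")]
    if group is not None:
        cols = [c for c in cols if c.startswith(f"spc_{group}_")]
    return cols


def pep_columns(table: pd.DataFrame, group: str | None = None) -> list[str]:
    cols = [c for c in table.columns if c.startswith("pep_")]
    if group is not None:
        cols = [c for c in cols if c.startswith(f"pep_{group}_")]
    return cols


def _validate_table(table: pd.DataFrame) -> None:
    for col in ("protein_id", "length_aa"):
        if col not in table.columns:
            raise ValueError(f"count table is missing required column {col!r}")
    if (table["length_aa"] <= 0).any():
        raise ValueError("protein lengths must be positive")
    if not spc_columns(table):
        raise ValueError("count table has no spc_<group>_<rep> columns")


def read_counts_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    _validate_table(table)
    return table


def filter_by_peptides(table: pd.DataFrame, min_peptides: int = 3) -> pd.DataFrame:
    """Keep proteins with >= min_peptides summed peptide identifications.

    The sum runs over all samples of both groups (the "among the six
    samples" rule for the 3-vs-3 design); row order is preserved.
    """
    if min_peptides < 1:
        raise ValueError("min_peptides must be >= 1")
    if table.empty:
        return table.copy()
    pep = pep_columns(table)
    if not pep:
        raise ValueError("count table has no pep_<group>_<rep> columns")
    total = table[pep].sum(axis=1)
    return table.loc[total >= min_peptides].reset_index(drop=True)


def compute_nsaf(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample NSAF matrix, indexed by protein_id.

    Each sample column sums to 1 over the proteins detected in it. A sample
    with no detected protein at all yields an all-zero column and a warning.
    """
    _validate_table(table)
    if table.empty:
        raise ValueError("cannot compute NSAF on an empty table")
    lengths = table["length_aa"].to_numpy(dtype=float)
    out = {}
    for col in spc_columns(table):
        saf = table[col].to_numpy(dtype=float) / lengths
        total = saf.sum()
        if total == 0:
            warnings.warn(f"sample {col!r} has no detected proteins; "
                          "its NSAF column is all zero", stacklevel=2)
            out[col.replace("spc_", "nsaf_")] = saf
        else:
            out[col.replace("spc_", "nsaf_")] = saf / total
    return pd.DataFrame(out, index=pd.Index(table["protein_id"], name="protein_id"))


def impute_missing(nsaf: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Force NSAF to exactly 0 wherever the protein was not identified.

    NSAF of an undetected protein is already 0 by construction; this makes
    the imputation rule explicit and guards externally supplied matrices.
    """
    if len(nsaf) != len(table):
        raise ValueError("NSAF matrix and count table differ in length")
    out = nsaf.copy()
    for col in spc_columns(table):
        ncol = col.replace("spc_", "nsaf_")
        out.loc[(table[col].to_numpy() == 0), ncol] = 0.0
    return out


def _group_values(nsaf: pd.DataFrame, group: str) -> np.ndarray:
    cols = [c for c in nsaf.columns if c.startswith(f"nsaf_{group}_")]
    if len(cols) < 2:
        raise ValueError(f"group {group!r} needs at least 2 samples")
    return nsaf[cols].to_numpy(dtype=float)


def log2_fold_change(nsaf: pd.DataFrame) -> pd.Series:
    """log2 of MF-mean NSAF over P2-mean NSAF, per protein.

    Proteins exclusive to MF (P2 mean 0, MF mean > 0) carry +inf; proteins
    exclusive to P2 carry -inf; proteins with both means 0 carry NaN.
    """
    mf = _group_values(nsaf, GROUP_MF).mean(axis=1)
    p2 = _group_values(nsaf, GROUP_P2).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mf / p2)
    lfc[(mf == 0) & (p2 == 0)] = np.nan
    return pd.Series(lfc, index=nsaf.index, name="log2fc")


def protein_t_test(nsaf: pd.DataFrame, welch: bool = False,
                   log_transform: bool = False) -> pd.Series:
    """Two-sided two-sample t test on per-group NSAF values, per protein.

    Equal-variance (Student) by default, Welch behind a flag; imputed zeros
    participate as real values. Degenerate rows where both groups are
    constant get p = 1 if the constants agree and p = 0 if they differ
    (keeps exclusively detected proteins testable).
    """
    mf = _group_values(nsaf, GROUP_MF)
    p2 = _group_values(nsaf, GROUP_P2)
    if log_transform:
        # log2(NSAF + eps): eps one order below the smallest nonzero NSAF.
        nonzero = np.concatenate([mf[mf > 0], p2[p2 > 0]])
        eps = (nonzero.min() / 10.0) if nonzero.size else 1e-12
        mf = np.log2(mf + eps)
        p2 = np.log2(p2 + eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(mf, p2, axis=1, equal_var=not welch)
        p = np.asarray(res.pvalue, dtype=float)

    degenerate = (mf.std(axis=1) == 0) & (p2.std(axis=1) == 0)
    equal_const = degenerate & (mf.mean(axis=1) == p2.mean(axis=1))
    p[degenerate & ~equal_const] = 0.0
    p[equal_const] = 1.0
    p[np.isnan(p)] = 1.0
    return pd.Series(p, index=nsaf.index, name="p_value")


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, int]:
    """Benjamini-Hochberg q-values and the FDR cutoff rank.

    Returns ``(q_values, cutoff_rank)`` where q_(i) = min_{j>=i} p_(j)*m/j
    along the ascending-p ranking and ``cutoff_rank`` is the deepest rank
    whose q-value is <= alpha (0 when no protein passes). All proteins at
    rank <= cutoff_rank are within the alpha FDR set.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), 0
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p, alpha=alpha, method="fdr_bh")[1]
    cutoff_rank = int((q <= alpha).sum())
    return q, cutoff_rank


@dataclass
class EnrichmentSummary:
    """Dataset-level counts reported alongside the per-protein table."""

    n_proteins: int
    n_shared: int
    n_mf_exclusive: int
    n_p2_exclusive: int
    n_enriched_significant: int      # shared, log2fc > 0, p <= alpha
    n_exclusive_significant: int     # MF-exclusive with p <= alpha
    n_high_confidence: int           # within the BH alpha-FDR cutoff
    frac_mf_exclusive: float
    frac_p2_exclusive: float


def classify_and_report(table: pd.DataFrame, nsaf: pd.DataFrame,
                        log2fc: pd.Series, p: pd.Series, q: np.ndarray,
                        alpha: float = 0.05,
                        ) -> tuple[pd.DataFrame, EnrichmentSummary]:
    """Assemble the per-protein enrichment table and summary counts.

    Detection classes: ``shared`` (counts in both groups), ``MF-exclusive``
    / ``P2-exclusive`` (all counts of the other group zero), and
    ``undetected-after-filter``. ``significant`` is p <= alpha;
    ``high_confidence`` marks proteins whose q-value is within the BH
    alpha-FDR cutoff.
    """
    n = len(table)
    if not (len(nsaf) == len(log2fc) == len(p) == len(q) == n):
        raise ValueError("misaligned inputs: all tables must cover the same proteins")
    if not (nsaf.index.to_numpy() == table["protein_id"].to_numpy()).all():
        raise ValueError("misaligned inputs: protein order differs")

    mf_any = table[spc_columns(table, GROUP_MF)].sum(axis=1).to_numpy() > 0
    p2_any = table[spc_columns(table, GROUP_P2)].sum(axis=1).to_numpy() > 0
    detection = np.where(
        mf_any & p2_any, CLASS_SHARED,
        np.where(mf_any, CLASS_MF_EXCLUSIVE,
                 np.where(p2_any, CLASS_P2_EXCLUSIVE, CLASS_UNDETECTED)))

    p_arr = p.to_numpy()
    lfc = log2fc.to_numpy()
    significant = p_arr <= alpha
    high_confidence = np.asarray(q) <= alpha

    out = pd.DataFrame({
        "protein_id": table["protein_id"].to_numpy(),
        "log2fc": lfc,
        "p_value": p_arr,
        "q_value": np.asarray(q),
        "detection_class": detection,
        "significant": significant,
        "high_confidence": high_confidence,
    })

    shared = detection == CLASS_SHARED
    mf_excl = detection == CLASS_MF_EXCLUSIVE
    p2_excl = detection == CLASS_P2_EXCLUSIVE
    summary = EnrichmentSummary(
        n_proteins=n,
        n_shared=int(shared.sum()),
        n_mf_exclusive=int(mf_excl.sum()),
        n_p2_exclusive=int(p2_excl.sum()),
        n_enriched_significant=int((shared & (lfc > 0) & significant).sum()),
        n_exclusive_significant=int((mf_excl & significant).sum()),
        n_high_confidence=int(high_confidence.sum()),
        frac_mf_exclusive=float(mf_excl.sum()) / n if n else float("nan"),
        frac_p2_exclusive=float(p2_excl.sum()) / n if n else float("nan"),
    )
    return out, summary


def run_enrichment(table: pd.DataFrame, min_peptides: int = 3,
                   alpha: float = 0.05, welch: bool = False,
                   log_transform: bool = False,
                   ) -> tuple[pd.DataFrame, EnrichmentSummary]:
    """Full pipeline: filter -> NSAF -> impute -> log2FC -> t -> BH -> report."""
    filtered = filter_by_peptides(table, min_peptides=min_peptides)
    if filtered.empty:
        empty = pd.DataFrame(columns=["protein_id", "log2fc", "p_value",
                                      "q_value", "detection_class",
                                      "significant", "high_confidence"])
        return empty, EnrichmentSummary(0, 0, 0, 0, 0, 0, 0,
                                        float("nan"), float("nan"))
    nsaf = impute_missing(compute_nsaf(filtered), filtered)
    lfc = log2_fold_change(nsaf)
    p = protein_t_test(nsaf, welch=welch, log_transform=log_transform)
    q, _ = bh_adjust(p.to_numpy(), alpha=alpha)
    return classify_and_report(filtered, nsaf, lfc, p, q, alpha=alpha)


def write_enrichment_tsv(result: pd.DataFrame, path) -> None:
    """Serialize; infinite fold changes round-trip as literal 'Inf'/'-Inf'."""
    out = result.copy()
    out["log2fc"] = out["log2fc"].map(
        lambda v: "Inf" if v == np.inf else ("-Inf" if v == -np.inf else v))
    out.to_csv(path, sep="\t", index=False)
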