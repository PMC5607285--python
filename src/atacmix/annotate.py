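"""Peak annotation relative to gene TSSs and peak-gene fold-change coupling.

Peaks are classified as promoter (distance to the nearest TSS <= 2 kb) or
distal (> 2 kb), distance being measured from the TSS to the nearest covered
base of the peak (0 when the TSS falls inside the interval). For one-to-one
peak/gene comparisons each gene is represented by its linked peak with the
largest absolute accessibility log2 fold change.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .containers import PeakSet

__all__ = [
    "annotate_tss_distance",
    "assign_peak_to_gene",
    "fold_change_concordance",
    "PROMOTER_MAX_DISTANCE",
]

logger = logging.getLogger(__name__)

PROMOTER_MAX_DISTANCE = 2000  # bp


def annotate_tss_distance(peaks: PeakSet, tss: pd.DataFrame) -> pd.DataFrame:
    """Nearest gene, TSS distance and promoter/distal class per peak.

    ``tss`` is gene_id-indexed with columns chrom, position, strand. The
    distance is 0 when a TSS lies inside the peak, otherwise the gap between
    the TSS and the nearest peak edge. Peaks on chromosomes without any TSS
    get distance inf and class distal, with a warning.
    """
    out = []
    by_chrom = {c: sub.sort_values("position") for c, sub in tss.groupby("chrom")}
    n_orphan = 0
    for pid, row in peaks.df.iterrows():
        sub = by_chrom.get(row["chrom"])
        if sub is None:
            n_orphan += 1
            out.append((pid, None, np.inf, "distal"))
            continue
        pos = sub["position"].to_numpy()
        start, end = row["start"], row["end"]
        # distance from each TSS to interval [start, end); 0 if inside
        d = np.maximum.reduce([start - pos, pos - (end - 1), np.zeros_like(pos)])
        i = int(np.argmin(d))
        dist = int(d[i])
        cls = "promoter" if dist <= PROMOTER_MAX_DISTANCE else "distal"
        out.append((pid, sub.index[i], dist, cls))
    if n_orphan:
        logger.warning("%d peak(s) on chromosomes with no annotated TSS", n_orphan)
    res = pd.DataFrame(
        out, columns=["peak_id", "nearest_gene", "tss_distance", "peak_class"]
    ).set_index("peak_id")
    return res


def assign_peak_to_gene(
    peak_fold_changes: pd.Series,
    peak_gene_links: pd.Series,
    mean_accessibility: pd.Series | None = None,
) -> pd.Series:
    """Pick one representative peak per gene: the max |log2 FC| linked peak.

    ``peak_gene_links`` maps peak_id -> gene_id (from nearest-TSS
    annotation). Ties on |FC| break toward the larger raw mean
    accessibility, then lexicographically smaller peak_id. Genes with no
    linked peak are simply absent from the result.
    """
    links = peak_gene_links.dropna()
    fc = peak_fold_changes.reindex(links.index)
    if fc.isna().any():
        missing = fc.index[fc.isna()].tolist()[:5]
        raise KeyError(f"fold change missing for linked peaks: {missing}")
    table = pd.DataFrame({"gene": links, "abs_fc": fc.abs()})
    table["mean_acc"] = (
        mean_accessibility.reindex(links.index).fillna(0.0)
        if mean_accessibility is not None
        else 0.0
    )
    table = table.sort_index().sort_values(
        ["abs_fc", "mean_acc"], ascending=[False, False], kind="stable"
    )
    best = table.groupby("gene", sort=True).head(1)
    return pd.Series(best.index, index=best["gene"], name="peak_id")


def fold_change_concordance(
    peak_fc: pd.Series,
    expression_fc: pd.Series,
    restrict_to=None,
) -> tuple[float, int]:
    """Pearson correlation between per-gene peak and expression fold changes.

    Both series are gene_id-indexed; only genes present in both are used.
    ``restrict_to`` optionally limits the comparison to a subset of genes
    (e.g. those with cell-specific accessibility and expression).
    """
    genes = peak_fc.index.intersection(expression_fc.index)
    if restrict_to is not None:
        genes = genes.intersection(pd.Index(restrict_to))
    n = len(genes)
    if n < 3:
        raise ValueError(f"need >= 3 paired genes, have {n}")
    r = float(pearsonr(peak_fc[genes].to_numpy(), expression_fc[genes].to_numpy())[0])
    return r, n
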