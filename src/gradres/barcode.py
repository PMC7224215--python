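"""Clone tracing with neutral DNA barcodes: enrichment, diversity, structure.

A barcode count table (barcodes x samples, with two baseline aliquot
samples and one sample per condition x replicate) is analysed for
evidence of pre-existing drug-tolerant clones:

* a clone counts as *positively selected* in a sample when its frequency
  strictly exceeds the highest barcode frequency in the element-wise
  average of the baseline samples;
* clonal selection is summarised by the Shannon diversity index
  H = -sum f ln f (nats), which drops as few clones take over;
* pre-existence shows up as high Spearman correlation of the selected
  barcodes' frequencies between replicates of the same condition, and
  low correlation across conditions;
* hierarchical clustering of the selected barcodes groups samples by
  the clone sets they expanded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

__all__ = [
    "BarcodeTable",
    "EnrichmentResult",
    "ClusterResult",
    "enrichment_threshold",
    "call_enriched",
    "shannon_diversity",
    "replicate_correlation",
    "cluster_enriched",
]

BASELINE_ROLE = "baseline"


class BarcodeTable:
    """Barcode x sample read counts with per-sample role labels.

    ``counts`` is a DataFrame (index: barcode ids, columns: sample
    names); ``roles`` maps every sample to ``"baseline"`` or a condition
    label.  Frequencies are computed per sample as count / total before
    any filtering.
    """

    def __init__(self, counts: pd.DataFrame, roles: dict):
        if set(counts.columns) != set(roles):
            raise ValueError("roles must label exactly the table's samples")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise ValueError(f"samples with zero total reads: {bad}")
        self.counts = counts
        self.roles = dict(roles)
        self.freq = counts / totals

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    @property
    def baseline_samples(self) -> list:
        return [s for s in self.samples if self.roles[s] == BASELINE_ROLE]

    @property
    def treated_samples(self) -> list:
        return [s for s in self.samples if self.roles[s] != BASELINE_ROLE]

    def condition_of(self, sample: str) -> str:
        return self.roles[sample]

    # -- CSV round trip ---------------------------------------------------
    def to_csv(self, path) -> None:
        """Write counts with a second header row carrying the sample roles."""
        with open(path, "w") as fh:
            fh.write("barcode," + ",".join(self.samples) + "\n")
            fh.write("#role," + ",".join(self.roles[s] for s in self.samples) + "\n")
            self.counts.to_csv(fh, header=False)

    @classmethod
    def from_csv(cls, path) -> "BarcodeTable":
        with open(path) as fh:
            header = fh.readline().strip().split(",")
            role_row = fh.readline().strip().split(",")
            if not role_row or role_row[0] != "#role":
                raise ValueError("expected a '#role' row after the header")
            body = pd.read_csv(fh, header=None, names=header, index_col=0)
        samples = header[1:]
        roles = dict(zip(samples, role_row[1:]))
        return cls(body[samples].astype(np.int64), roles)


def enrichment_threshold(table: BarcodeTable) -> float:
    """Highest barcode frequency in the averaged baseline samples."""
    base = table.baseline_samples
    if not base:
        raise ValueError("table has no baseline samples")
    return float(table.freq[base].mean(axis=1).max())


@dataclass
class EnrichmentResult:
    """Per-sample positively selected barcode sets."""

    threshold: float
    enriched: dict  # sample -> pd.Index of barcode ids
    union: pd.Index  # barcodes enriched in >= 1 non-baseline sample

    def __post_init__(self):
        if not self.threshold > 0:
            raise AssertionError("enrichment threshold must be > 0")


def call_enriched(table: BarcodeTable, threshold: float | None = None) -> EnrichmentResult:
    """Barcodes whose frequency strictly exceeds the baseline-derived threshold.

    A barcode sitting exactly at the threshold is *not* called (strict
    inequality).  Only non-baseline samples are scanned.
    """
    if threshold is None:
        threshold = enrichment_threshold(table)
    enriched = {}
    union = pd.Index([], dtype=object)
    for s in table.treated_samples:
        hits = table.freq.index[table.freq[s] > threshold]
        enriched[s] = hits
        union = union.union(hits)
    return EnrichmentResult(threshold=float(threshold), enriched=enriched, union=union)


def shannon_diversity(frequencies) -> float:
    """Shannon diversity H = -sum f ln f in nats; zero frequencies drop out."""
    f = np.asarray(frequencies, dtype=float)
    if len(f) and abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must sum to 1")
    f = f[f > 0]
    return float(-(f * np.log(f)).sum())


def diversity_table(table: BarcodeTable) -> pd.Series:
    """Shannon diversity (nats) per sample."""
    return pd.Series(
        {s: shannon_diversity(table.freq[s].to_numpy()) for s in table.samples},
        name="H_nats",
    )


def replicate_correlation(result: EnrichmentResult, table: BarcodeTable) -> pd.DataFrame:
    """Pairwise Spearman correlation of enriched-barcode frequencies.

    Frequencies are restricted to the union of positively selected
    barcodes; all samples (baseline included) are compared.
    """
    if len(result.union) == 0:
        raise ValueError("no enriched barcodes: correlation undefined")
    if len(result.union) < 3:
        warnings.warn(
            f"only {len(result.union)} enriched barcodes; correlations are underpowered",
            stacklevel=2,
        )
    sub = table.freq.loc[result.union]
    # pairwise spearman via pandas: robust to constant columns (NaN entry)
    vals = sub.corr(method="spearman").to_numpy(copy=True)
    np.fill_diagonal(vals, 1.0)
    return pd.DataFrame(vals, index=sub.columns, columns=sub.columns)


@dataclass
class ClusterResult:
    """Row/column orderings and linkage trees for a clustered heatmap."""

    barcode_order: pd.Index
    sample_order: list
    barcode_linkage: np.ndarray | None
    sample_linkage: np.ndarray | None
    log_freq: pd.DataFrame


def cluster_enriched(
    result: EnrichmentResult, table: BarcodeTable, pseudofreq: float | None = None
) -> ClusterResult:
    """Agglomerative clustering of the selected barcodes and samples.

    Complete linkage on Euclidean distances of log10 frequencies (a
    half-read pseudofrequency guards the zeros).  Barcodes are rows,
    non-baseline samples are columns.
    """
    if len(result.union) == 0:
        raise ValueError("no enriched barcodes to cluster")
    cols = table.treated_samples
    sub = table.freq.loc[result.union, cols]
    if pseudofreq is None:
        pseudofreq = float(0.5 / table.counts[cols].sum(axis=0).max())
    mat = np.log10(sub.to_numpy() + pseudofreq)
    if mat.shape[0] > 1:
        row_link = linkage(mat, method="complete", metric="euclidean")
        row_order = sub.index[leaves_list(row_link)]
    else:
        row_link = None
        row_order = sub.index
    if mat.shape[1] > 1:
        col_link = linkage(mat.T, method="complete", metric="euclidean")
        col_order = [cols[i] for i in leaves_list(col_link)]
    else:
        col_link = None
        col_order = list(cols)
    return ClusterResult(
        barcode_order=row_order,
        sample_order=col_order,
        barcode_linkage=row_link,
        sample_linkage=col_link,
        log_freq=pd.DataFrame(mat, index=sub.index, columns=cols),
    )
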