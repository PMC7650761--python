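"""Virus abundance: EM over multi-mapped reads, TPM, tiers, index-hop filter.

Reads that map ambiguously across contigs are resolved with a desk-scale
expectation-maximization quantifier in the style of RSEM: the E-step
splits each ambiguous read class across its compatible contigs in
proportion to current abundance per effective nucleotide (theta_i /
ell_i), the M-step re-estimates theta as the expected counts.  Effective
length is taken as the contig length — no fragment-length correction.

Abundance per virus per library is expressed as the percentage of the
library's total reads and binned into the study's three tiers:
high > 0.01%, moderate in (0.001%, 0.01%], low <= 0.001%.

Cross-library index hopping is filtered by removing a detection whose
count is below 0.1% of the reference count of the same virus in the
other libraries; the reference is the pooled (summed) count by default,
with the single highest count available as an alternative mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

HIGH_TIER_PERCENT = 0.01
MODERATE_TIER_PERCENT = 0.001
DEFAULT_HOP_THRESHOLD = 0.001  # 0.1% of the reference count


@dataclass(frozen=True)
class ReadClass:
    """A class of identically-mapping reads: its size and the contigs it
    is compatible with."""

    count: float
    contigs: tuple

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("read class count must be non-negative")
        if not self.contigs:
            raise ValueError("read class maps to no contig")


@dataclass
class CompatibilityTable:
    """Read classes over a universe of contigs with effective lengths."""

    classes: list
    effective_lengths: dict

    def __post_init__(self):
        if any(l <= 0 for l in self.effective_lengths.values()):
            raise ValueError("effective lengths must be positive")
        for rc in self.classes:
            unknown = set(rc.contigs) - set(self.effective_lengths)
            if unknown:
                raise ValueError(f"read class references unknown contigs {sorted(unknown)}")

    @property
    def contig_ids(self) -> list:
        return list(self.effective_lengths)

    @property
    def total_reads(self) -> float:
        return sum(rc.count for rc in self.classes)


@dataclass(frozen=True)
class VirusDetection:
    """One virus observed in one library."""

    virus_name: str
    library_id: str
    read_count: float
    effective_length: float
    tpm: float
    percent_total: float
    abundance_class: str


def em_quantify(
    table: CompatibilityTable,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    return_trace: bool = False,
):
    """Expected read count per contig by EM over ambiguous read classes.

    Iterates E (split each class proportionally to theta_i/ell_i over its
    compatible contigs) and M (theta <- expected counts) until
    ``max |dtheta| < tol`` or ``max_iter``.  Expected counts always sum to
    the total read count.  With ``return_trace`` the per-iteration
    log-likelihood is returned as well (non-decreasing, up to round-off).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    contigs = table.contig_ids
    idx = {c: i for i, c in enumerate(contigs)}
    n = len(contigs)
    lengths = np.array([table.effective_lengths[c] for c in contigs], dtype=float)
    class_counts = np.array([rc.count for rc in table.classes], dtype=float)
    members = [np.array([idx[c] for c in rc.contigs]) for rc in table.classes]
    total = class_counts.sum()
    if total == 0 or n == 0:
        counts = {c: 0.0 for c in contigs}
        return (counts, []) if return_trace else counts

    theta = np.full(n, total / n)
    trace = []
    for _ in range(max_iter):
        rate = theta / lengths
        expected = np.zeros(n)
        loglik = 0.0
        for cnt, mem in zip(class_counts, members):
            w = rate[mem]
            s = w.sum()
            if s == 0:
                # degenerate: class's contigs all at zero; split uniformly
                expected[mem] += cnt / len(mem)
                continue
            expected[mem] += cnt * w / s
            # model: pick a transcript by fraction theta/total, then a
            # start position uniformly, so P(read r) = sum nu_i / l_i
            loglik += cnt * np.log(s / total)
        trace.append(loglik)
        delta = np.abs(expected - theta).max()
        theta = expected
        if delta < tol:
            break
    counts = {c: float(theta[i]) for c, i in idx.items()}
    return (counts, trace) if return_trace else counts


def tpm(expected_counts: Sequence[float], effective_lengths: Sequence[float]) -> np.ndarray:
    """Transcripts per million: ``(c_i/l_i) / sum_j(c_j/l_j) * 1e6``.

    Sums to 1e6; an all-zero count vector maps to an all-zero TPM vector.
    """
    counts = np.asarray(expected_counts, dtype=float)
    lengths = np.asarray(effective_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must align")
    rate = counts / lengths
    denom = rate.sum()
    if denom == 0:
        return np.zeros_like(rate)
    return rate / denom * 1e6


def percent_of_total(virus_read_count: float, library_total_reads: float) -> float:
    """Virus abundance as a percentage of the library's total read count."""
    if library_total_reads <= 0:
        raise ValueError("library total reads must be positive")
    if virus_read_count < 0:
        raise ValueError("read count must be non-negative")
    if virus_read_count > library_total_reads:
        raise ValueError(
            f"virus read count {virus_read_count} exceeds library total {library_total_reads}"
        )
    return 100.0 * virus_read_count / library_total_reads


def classify_abundance(percent_total: float) -> str:
    """Bin a percent-of-total-reads abundance into high/moderate/low.

    Strictly greater than 0.01% is high; (0.001%, 0.01%] moderate;
    anything at or below 0.001% is low.
    """
    if percent_total < 0:
        raise ValueError("percent abundance cannot be negative")
    if percent_total > HIGH_TIER_PERCENT:
        return "high"
    if percent_total > MODERATE_TIER_PERCENT:
        return "moderate"
    return "low"


@dataclass(frozen=True)
class HopRemoval:
    virus_name: str
    library_id: str
    count: int
    reference_count: int
    threshold: float


def contamination_filter(
    count_matrix: pd.DataFrame,
    threshold_fraction: float = DEFAULT_HOP_THRESHOLD,
    mode: str = "sum",
) -> tuple[pd.DataFrame, list[HopRemoval]]:
    """Remove putative index-hop detections from a virus × library matrix.

    A detection (virus v, library L) is removed iff its count is positive
    and below ``threshold_fraction`` times the reference count of v in the
    other libraries — pooled over them (``mode='sum'``, default) or the
    single largest (``mode='max'``).  Removed cells are zeroed; removals
    are itemized.  A virus seen in only one library is never removed.
    """
    if mode not in {"sum", "max"}:
        raise ValueError("mode must be 'sum' or 'max'")
    values = count_matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("count matrix must be non-negative")
    filtered = count_matrix.copy()
    removals: list[HopRemoval] = []
    for virus, row in count_matrix.iterrows():
        counts = row.to_numpy(dtype=float)
        for j, lib in enumerate(count_matrix.columns):
            c = counts[j]
            if c <= 0:
                continue
            others = np.delete(counts, j)
            ref = others.sum() if mode == "sum" else (others.max() if others.size else 0.0)
            if ref <= 0:
                continue
            cutoff = threshold_fraction * ref
            if c < cutoff:
                filtered.loc[virus, lib] = 0
                removals.append(
                    HopRemoval(str(virus), str(lib), int(c), int(ref), cutoff)
                )
    return filtered, removals


def detections_from_matrix(
    count_matrix: pd.DataFrame,
    library_totals: dict,
    virus_lengths: dict | None = None,
) -> list[VirusDetection]:
    """Turn a filtered count matrix into per-detection records with
    percent-of-total and abundance tier.  TPM is computed within each
    library over the viruses quantified there."""
    detections: list[VirusDetection] = []
    for lib in count_matrix.columns:
        col = count_matrix[lib]
        total = library_totals[lib]
        lengths = np.array(
            [virus_lengths.get(v, 1000.0) if virus_lengths else 1000.0 for v in col.index]
        )
        tpms = tpm(col.to_numpy(dtype=float), lengths)
        for virus, cnt, t, l in zip(col.index, col.to_numpy(dtype=float), tpms, lengths):
            if cnt <= 0:
                continue
            pct = percent_of_total(cnt, total)
            detections.append(
                VirusDetection(
                    virus_name=str(virus),
                    library_id=str(lib),
                    read_count=float(cnt),
                    effective_length=float(l),
                    tpm=float(t),
                    percent_total=pct,
                    abundance_class=classify_abundance(pct),
                )
            )
    return detections
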