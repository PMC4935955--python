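"""Backcross linkage mapping of a fully penetrant recessive binary trait.

In a [(mut x mapping-strain)F1 x mut] backcross every offspring is either
homozygous mutant-strain (M) or heterozygous (H) at each marker, and for a
fully penetrant recessive trait the causal-locus genotype is read off the
phenotype: affected animals are M, unaffected are H.  A recombinant at a
marker is therefore any (affected, H) or (unaffected, M) animal, the MLE of
the recombination fraction is theta_hat = r/n, and the two-point backcross
LOD is

    LOD = log10[ theta_hat^r (1 - theta_hat)^(n-r) / 0.5^n ]

with the convention 0^0 = 1.  The critical interval is delimited by the
nearest markers flanking the LOD peak that exhibit at least one recombinant
(a recombinant at a flanking marker places the causal locus on its peak-ward
side); chromosome ends are used when no flanking recombinant marker exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .model import GenomicInterval, MarkerGenotypeTable


@dataclass
class MarkerLinkage:
    marker_id: str
    chrom: str
    pos: int
    informative_count: int
    recombinant_count: int
    theta_hat: float
    lod: float


@dataclass
class LinkageResult:
    per_marker: list[MarkerLinkage]
    peak_marker_id: Optional[str] = None
    critical_interval: Optional[GenomicInterval] = None
    linked: bool = True

    def marker(self, marker_id: str) -> MarkerLinkage:
        for m in self.per_marker:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)


def count_recombinants(
    marker_calls: Sequence[Optional[str]], affected: Sequence[bool]
) -> tuple[int, int]:
    """Count recombinants (r) and informative animals (n) for one marker.

    Missing calls (None) are excluded from n rather than imputed.
    """
    if len(marker_calls) != len(affected):
        raise ValueError("marker calls and phenotype vector differ in length")
    r = 0
    n = 0
    for call, is_affected in zip(marker_calls, affected):
        if call is None:
            continue
        if call not in ("M", "H"):
            raise ValueError(f"unknown genotype code {call!r}")
        n += 1
        if (is_affected and call == "H") or (not is_affected and call == "M"):
            r += 1
    if n == 0:
        raise ValueError("all marker calls missing; no informative animals")
    return r, n


def backcross_lod(r: int, n: int) -> float:
    """Two-point backcross LOD at the MLE theta_hat = r/n (0^0 := 1)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= r <= n:
        raise ValueError(f"need 0 <= r <= n, got r={r}, n={n}")
    theta = r / n
    log_lik = 0.0
    if r > 0:
        log_lik += r * math.log10(theta)
    if n - r > 0:
        log_lik += (n - r) * math.log10(1.0 - theta)
    return log_lik + n * math.log10(2.0)


def map_critical_interval(
    table: MarkerGenotypeTable,
    affected: Sequence[bool],
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> LinkageResult:
    """Two-point scan over all markers plus flanking-recombinant interval.

    The peak is the marker with maximal LOD (ties broken toward the smaller
    genomic position, i.e. the proximal marker).  If no marker shows positive
    LOD a "no linkage" result with an empty interval is returned.
    """
    if len(affected) != len(table.animals):
        raise ValueError("phenotype vector length does not match animal list")
    per_marker: list[MarkerLinkage] = []
    for marker in table.markers:
        r, n = count_recombinants(table.column(marker.marker_id), affected)
        per_marker.append(
            MarkerLinkage(
                marker_id=marker.marker_id,
                chrom=marker.chrom,
                pos=marker.pos,
                informative_count=n,
                recombinant_count=r,
                theta_hat=r / n,
                lod=backcross_lod(r, n),
            )
        )
    peak = min(per_marker, key=lambda m: (-m.lod, m.chrom, m.pos))
    if peak.lod <= 0.0:
        return LinkageResult(per_marker=per_marker, linked=False)

    chrom_markers = sorted(
        (m for m in per_marker if m.chrom == peak.chrom), key=lambda m: m.pos
    )
    if len(chrom_markers) < 3:
        raise ValueError(
            f"need >= 3 markers on the peak chromosome {peak.chrom}, "
            f"got {len(chrom_markers)}"
        )
    peak_idx = next(
        i for i, m in enumerate(chrom_markers) if m.marker_id == peak.marker_id
    )
    start: Optional[int] = None
    for m in reversed(chrom_markers[:peak_idx]):
        if m.recombinant_count >= 1:
            start = m.pos
            break
    end: Optional[int] = None
    for m in chrom_markers[peak_idx + 1 :]:
        if m.recombinant_count >= 1:
            end = m.pos
            break
    if start is None:
        start = 1
    if end is None:
        if chrom_lengths and peak.chrom in chrom_lengths:
            end = chrom_lengths[peak.chrom]
        else:
            end = chrom_markers[-1].pos
    return LinkageResult(
        per_marker=per_marker,
        peak_marker_id=peak.marker_id,
        critical_interval=GenomicInterval(peak.chrom, start, max(start, end)),
        linked=True,
    )
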