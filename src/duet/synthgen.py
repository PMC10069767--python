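"""Synthetic ground-truth generators for the double-infection analyses.

Three generators provide every input the downstream stages need, with
known truth:

* :func:`make_strain_pair` — two closely related circular symbiont genomes
  sharing a backbone, with strain-private regions and copy-number variant
  intervals, plus a truth table of every diverged interval;
* :func:`simulate_mixture_depth` — per-base Poisson sequencing depth of a
  two-strain mixture aligned to the strain-A assembly, at a set titer
  fraction (coverage is simulated as independent per-base Poisson counts,
  the Lander–Waterman expectation; depth is the sufficient statistic the
  deconvolution consumes, so no read placement is modelled);
* :func:`simulate_backcross_genotypes` — genotypes of backcross-derived
  females segregating a single dominant suppressor locus, with phenotype
  labels and the truth locus.

Coordinates are 1-based with inclusive starts and exclusive ends
throughout; exported BED converts to 0-based half-open.  All generators
take explicit seeds (default 42) and are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .depthdeconv import DepthTrack
from .sweepscan import MISSING, GenotypeMatrix

__all__ = [
    "StrainPairSpec",
    "CoverageSimSpec",
    "BackcrossSimSpec",
    "StrainPair",
    "BackcrossPanel",
    "make_strain_pair",
    "simulate_mixture_depth",
    "simulate_backcross_genotypes",
]

Interval = tuple[int, int]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _check_intervals(intervals, backbone_length: int, name: str) -> None:
    for s, e in intervals:
        if not (1 <= s < e <= backbone_length + 1):
            raise ValueError(
                f"{name} interval [{s}, {e}) outside [1, {backbone_length + 1})"
            )


def _check_no_overlap(labelled: list[tuple[str, Interval]]) -> None:
    ordered = sorted(labelled, key=lambda t: t[1][0])
    for (na, (sa, ea)), (nb, (sb, eb)) in zip(ordered, ordered[1:]):
        if sb < ea:
            raise ValueError(
                f"overlapping intervals: {na} [{sa}, {ea}) and {nb} [{sb}, {eb})"
            )


@dataclass(frozen=True)
class StrainPairSpec:
    """Ground-truth layout of a two-strain pair.

    ``private_regions_a`` are backbone intervals present only in strain A
    (the reference strain); ``private_regions_b`` give the anchor and
    length of novel sequence present only in strain B (inserted at the
    interval's start — such sequence has no reference coordinates and the
    depth analysis cannot see it).  ``cnv_regions`` are
    (interval, copies_in_a, copies_in_b) triples.  ``titer_a`` is the
    fraction of all symbiont cells that belong to strain A.
    """

    backbone_length: int
    private_regions_a: tuple[Interval, ...] = ()
    private_regions_b: tuple[Interval, ...] = ()
    cnv_regions: tuple[tuple[Interval, int, int], ...] = ()
    titer_a: float = 0.7
    seed: int = 42

    def __post_init__(self) -> None:
        if self.backbone_length < 1:
            raise ValueError("backbone_length must be positive")
        if not 0.0 <= self.titer_a <= 1.0:
            raise ValueError("titer_a must lie in [0, 1]")
        _check_intervals(self.private_regions_a, self.backbone_length, "private_a")
        _check_intervals(self.private_regions_b, self.backbone_length, "private_b")
        _check_intervals([iv for iv, _, _ in self.cnv_regions],
                         self.backbone_length, "cnv")
        for iv, ca, cb in self.cnv_regions:
            if ca < 0 or cb < 0:
                raise ValueError("copy numbers must be non-negative")
        _check_no_overlap(
            [("private_a", iv) for iv in self.private_regions_a]
            + [("private_b", iv) for iv in self.private_regions_b]
            + [("cnv", iv) for iv, _, _ in self.cnv_regions]
        )


@dataclass(frozen=True)
class CoverageSimSpec:
    """Poisson coverage parameters: ``mean_depth`` is the expected per-base
    depth of single-copy shared sequence (the Poisson mean)."""

    mean_depth: float = 50.0
    window: int = 1000
    step: int = 500
    seed: int = 42

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not self.window >= self.step >= 1:
            raise ValueError("require window >= step >= 1")


@dataclass
class StrainPair:
    """Output of :func:`make_strain_pair`: the two genomes and the truth
    table (columns start, end, kind, copies_a, copies_b; 1-based,
    end-exclusive, on strain-A/backbone coordinates)."""

    genome_a: SeqRecord
    genome_b: SeqRecord
    truth: pd.DataFrame
    spec: StrainPairSpec


def make_strain_pair(spec: StrainPairSpec) -> StrainPair:
    """Build the two strain genomes and the interval truth table.

    Strain A is the backbone itself (private-A intervals are simply part
    of it) with CNV intervals tandem-repeated to ``copies_in_a``; strain B
    is the backbone minus the A-private intervals, with its own CNV copy
    counts and novel B-private insertions.
    """
    rng = np.random.default_rng(spec.seed)
    backbone = rng.choice(_BASES, size=spec.backbone_length)

    events: list[tuple[int, int, str, int, int]] = []
    for s, e in spec.private_regions_a:
        events.append((s, e, "private_a", 1, 0))
    for s, e in spec.private_regions_b:
        events.append((s, e, "private_b", 0, 1))
    for (s, e), ca, cb in spec.cnv_regions:
        events.append((s, e, "cnv", ca, cb))
    events.sort()

    parts_a: list[np.ndarray] = []
    parts_b: list[np.ndarray] = []
    cursor = 1
    for s, e, kind, ca, cb in events:
        shared = backbone[cursor - 1 : s - 1]
        parts_a.append(shared)
        parts_b.append(shared)
        segment = backbone[s - 1 : e - 1]
        if kind == "private_a":
            parts_a.append(segment)
        elif kind == "private_b":
            # backbone bases stay shared; novel sequence is inserted in B
            parts_a.append(segment)
            parts_b.append(rng.choice(_BASES, size=e - s))
            parts_b.append(segment)
        else:  # cnv
            parts_a.extend([segment] * ca)
            parts_b.extend([segment] * cb)
        cursor = e
    tail = backbone[cursor - 1 :]
    parts_a.append(tail)
    parts_b.append(tail)

    def _record(parts: list[np.ndarray], name: str) -> SeqRecord:
        seq = b"".join(p.tobytes() for p in parts).decode("ascii")
        return SeqRecord(Seq(seq), id=name, description="")

    truth = pd.DataFrame(
        events, columns=["start", "end", "kind", "copies_a", "copies_b"]
    )
    return StrainPair(
        genome_a=_record(parts_a, "strainA"),
        genome_b=_record(parts_b, "strainB"),
        truth=truth,
        spec=spec,
    )


def expected_multiplier(pair: StrainPair, titer_a: float | None = None) -> np.ndarray:
    """Expected depth multiplier per reference (strain-A backbone) base.

    Shared single-copy bases have multiplier 1; A-private bases ``titer_a``;
    CNV bases ``titer_a * copies_a + (1 - titer_a) * copies_b``.  B-private
    insertions do not exist on reference coordinates.
    """
    t = pair.spec.titer_a if titer_a is None else titer_a
    mult = np.ones(pair.spec.backbone_length)
    for row in pair.truth.itertuples():
        sl = slice(row.start - 1, row.end - 1)
        if row.kind == "private_a":
            mult[sl] = t
        elif row.kind == "cnv":
            mult[sl] = t * row.copies_a + (1 - t) * row.copies_b
    return mult


def simulate_mixture_depth(
    pair: StrainPair,
    titer_a: float | None = None,
    cov: CoverageSimSpec = CoverageSimSpec(),
) -> DepthTrack:
    """Draw per-base Poisson depth of the mixture over strain-A coordinates.

    The Poisson mean at each base is ``mean_depth`` times the local
    expected multiplier (titer-weighted copy multiplicity); at titer 1.0
    the track is homogeneous, including over A-private regions.
    """
    t = pair.spec.titer_a if titer_a is None else titer_a
    if not 0.0 <= t <= 1.0:
        raise ValueError("titer_a must lie in [0, 1]")
    rng = np.random.default_rng(cov.seed)
    lam = cov.mean_depth * expected_multiplier(pair, t)
    depth = rng.poisson(lam)
    return DepthTrack(genome_id=pair.genome_a.id, depth=depth)


@dataclass(frozen=True)
class BackcrossSimSpec:
    """Design of the suppressor-mapping backcross panel.

    A donor line fixed for alternate alleles genome-wide and homozygous for
    the dominant suppressor S is crossed into a recurrent line and the F1
    females backcrossed ``n_backcrosses`` times to recurrent males.  Final
    females are phenotyped (MKS if they carry S, else MK) and genotyped at
    all sites.  ``recomb_rate`` is the expected crossovers per contig per
    meiosis (a nominal one-per-contig default; no species map is implied).
    """

    n_contigs: int = 3
    sites_per_contig: int = 500
    contig_length: int = 5_000_000
    suppressor_contig: int = 0
    suppressor_pos: int = 2_500_000
    recomb_rate: float = 1.0
    n_lines_mk: int = 24
    n_lines_mks: int = 24
    n_backcrosses: int = 2
    missing_rate: float = 0.02
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.sites_per_contig < 1:
            raise ValueError("need at least one contig and one site")
        if not 0 <= self.suppressor_contig < self.n_contigs:
            raise ValueError("suppressor_contig out of range")
        if not 1 <= self.suppressor_pos <= self.contig_length:
            raise ValueError("suppressor_pos must lie within the contig")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be non-negative")
        if self.n_backcrosses < 0:
            raise ValueError("n_backcrosses must be non-negative")


@dataclass
class BackcrossPanel:
    """Genotype matrix with phenotype labels plus the truth locus."""

    gm: GenotypeMatrix
    truth_contig: str
    truth_pos: int


def _gamete(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    positions: np.ndarray,
    contig_length: int,
    recomb_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiotic product: Poisson-count crossovers at uniform positions."""
    n_x = rng.poisson(recomb_rate)
    if n_x == 0:
        return hap_a.copy() if rng.integers(2) == 0 else hap_b.copy()
    breaks = np.sort(rng.integers(1, contig_length + 1, size=n_x))
    segment = np.searchsorted(breaks, positions, side="left")
    phase = (segment + rng.integers(2)) % 2
    return np.where(phase == 0, hap_a, hap_b)


def simulate_backcross_genotypes(spec: BackcrossSimSpec) -> BackcrossPanel:
    """Simulate the backcross panel and return genotypes, labels and truth.

    Each line is an independent pedigree: an F1 female (donor gamete over
    recurrent gamete) backcrossed ``n_backcrosses`` times.  Lineages are
    resampled until the final female's suppressor status matches the
    requested phenotype, mirroring classification of pooled backcross
    females by observed offspring sex ratio.  Before missingness, every
    MKS female is heterozygous at the truth locus and every MK female is
    homozygous recurrent there.
    """
    if spec.n_lines_mk + spec.n_lines_mks == 0:
        raise ValueError("empty matrix: no lines requested")
    rng = np.random.default_rng(spec.seed)

    contigs = [f"contig_{i + 1}" for i in range(spec.n_contigs)]
    positions: list[np.ndarray] = []
    for i in range(spec.n_contigs):
        if i == spec.suppressor_contig:
            others = rng.choice(
                spec.contig_length, size=spec.sites_per_contig - 1, replace=False
            ) + 1
            others = others[others != spec.suppressor_pos]
            pos = np.unique(np.append(others, spec.suppressor_pos))
            while pos.size < spec.sites_per_contig:  # collision refill
                extra = rng.integers(1, spec.contig_length + 1)
                pos = np.unique(np.append(pos, extra))
        else:
            pos = np.sort(
                rng.choice(spec.contig_length, size=spec.sites_per_contig,
                           replace=False) + 1
            )
        positions.append(pos)
    supp_idx = int(
        np.searchsorted(positions[spec.suppressor_contig], spec.suppressor_pos)
    )

    def _line(require_s: bool) -> list[np.ndarray]:
        while True:
            maternal = [np.ones(p.size, dtype=np.int8) for p in positions]
            paternal = [np.zeros(p.size, dtype=np.int8) for p in positions]
            for _ in range(spec.n_backcrosses):
                maternal = [
                    _gamete(m, f, p, spec.contig_length, spec.recomb_rate, rng)
                    for m, f, p in zip(maternal, paternal, positions)
                ]
            has_s = bool(maternal[spec.suppressor_contig][supp_idx])
            if has_s == require_s:
                return maternal  # paternal is all-recurrent; genotype == maternal

    lines = [(_line(False), "MK") for _ in range(spec.n_lines_mk)]
    lines += [(_line(True), "MKS") for _ in range(spec.n_lines_mks)]

    genotypes = np.stack(
        [np.concatenate(haps).astype(np.int8) for haps, _ in lines]
    )
    if spec.missing_rate > 0:
        mask = rng.random(genotypes.shape) < spec.missing_rate
        genotypes[mask] = MISSING

    sites = pd.DataFrame(
        {
            "contig": np.repeat(contigs, [p.size for p in positions]),
            "pos": np.concatenate(positions),
            "ref": "A",
            "alt": "T",
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"{ph}_{i:03d}" for i, (_, ph) in enumerate(lines)],
            "line": ["N101" if i % 2 == 0 else "B302" for i in range(len(lines))],
            "phenotype": [ph for _, ph in lines],
        }
    )
    gm = GenotypeMatrix(genotypes=genotypes, sites=sites, samples=samples)
    return BackcrossPanel(
        gm=gm,
        truth_contig=contigs[spec.suppressor_contig],
        truth_pos=spec.suppressor_pos,
    )
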