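"""Strain-replacement detection from short-read allele counts (aANI-lowFreq).

aANI-lowFreq approximates 1 − ANI between the dominant strain of a species
in sample *a* and the strains present in sample *b*, from per-position
allele counts on the species' core-genome contigs.  It is robust to
low-frequency strains because it only counts *a*-exclusive SNVs: positions
where some allele reaches >= 50% frequency in *a* (supported by >= 10
reads) while staying below 10% frequency in *b* — the 10% tolerance absorbs
sequencing errors and stray mis-aligned reads in *b*.

Distances are computed over "shared" regions only: positions with >= 10×
depth in both samples, on contigs where >= 80% of positions reach 10× in
both.  The distance is the count of a-exclusive SNVs divided by the shared
length; it is asymmetric (a→b vs b→a) by construction.

Strain replacement within a patient is called against an empirical
between-patient calibration: different patients typically carry different
strains of a species, so within-patient distances falling inside the
between-patient distribution indicate the arrival of a new dominant strain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import fisher_exact_2x2

__all__ = [
    "AlleleCounts",
    "SharedMask",
    "StrainDistance",
    "StrainConfig",
    "IntervalCall",
    "read_allele_counts_tsv",
    "write_allele_counts_tsv",
    "allele_counts_from_bam",
    "shared_mask",
    "count_exclusive_snvs",
    "aani_lowfreq",
    "pair_eligibility",
    "calibrate_between_patient",
    "classify_interval",
    "make_interval_calls",
    "event_association",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class StrainConfig:
    """Thresholds of the aANI-lowFreq procedure (defaults as published)."""

    min_cov: int = 10              # per-position depth for "shared"
    contig_frac: float = 0.80      # contig fraction at min_cov to qualify
    major_freq: float = 0.50       # majority-allele frequency in sample a
    major_min_reads: int = 10      # reads supporting the majority allele
    absent_freq: float = 0.10      # allele counts as absent in b below this
    min_shared_core: float = 0.50  # eligible pairs: shared core fraction
    min_between_n: int = 10        # calibration distances required
    replacement_quantile: float = 0.05

    def __post_init__(self):
        for name in (
            "contig_frac",
            "major_freq",
            "absent_freq",
            "min_shared_core",
            "replacement_quantile",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_cov < 1 or self.major_min_reads < 1:
            raise ValueError("coverage thresholds must be >= 1")


class AlleleCounts:
    """Per-position A/C/G/T counts of one sample on core-genome contigs.

    ``counts[contig]`` is an integer array of shape (length, 4); depth at a
    position is the row sum (deletions and Ns are excluded upstream).
    """

    def __init__(
        self,
        sample_id: str,
        counts: Mapping[str, np.ndarray],
        contig_lengths: Mapping[str, int] | None = None,
    ):
        self.sample_id = sample_id
        self.counts: dict[str, np.ndarray] = {}
        for contig, arr in counts.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.ndim != 2 or arr.shape[1] != 4:
                raise ValueError(f"{contig}: counts must have shape (L, 4)")
            if (arr < 0).any():
                raise ValueError(f"{contig}: negative counts")
            expected = (contig_lengths or {}).get(contig)
            if expected is not None and arr.shape[0] != expected:
                raise ValueError(
                    f"{contig}: counts cover {arr.shape[0]} positions, "
                    f"contig length is {expected}"
                )
            self.counts[contig] = arr

    @property
    def contigs(self) -> list[str]:
        return sorted(self.counts)

    def depth(self, contig: str) -> np.ndarray:
        return self.counts[contig].sum(axis=1)

    def total_length(self) -> int:
        return sum(arr.shape[0] for arr in self.counts.values())


@dataclass(frozen=True)
class SharedMask:
    """Positions usable for a pairwise strain comparison."""

    masks: dict[str, np.ndarray]  # contig -> boolean per position
    shared_length: int
    core_length: int

    @property
    def shared_fraction(self) -> float:
        return self.shared_length / self.core_length if self.core_length else 0.0


@dataclass(frozen=True)
class StrainDistance:
    """aANI-lowFreq distance for an ordered sample pair a→b."""

    sample_a: str
    sample_b: str
    exclusive_snvs: int
    shared_length: int
    shared_core_fraction: float

    @property
    def aani_lowfreq(self) -> float | None:
        if self.shared_length == 0:
            return None
        return self.exclusive_snvs / self.shared_length


def read_allele_counts_tsv(
    source: str | Path | IO[str],
    sample_id: str,
    contig_lengths: Mapping[str, int] | None = None,
) -> AlleleCounts:
    """Load allele counts from TSV (columns: contig, pos, A, C, G, T).

    Positions are 0-based; omitted positions have zero depth.  Contig
    lengths come from ``contig_lengths`` when given, else from the maximum
    observed position per contig.
    """
    df = pd.read_csv(source, sep="\t")
    required = ["contig", "pos", "A", "C", "G", "T"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"allele-count TSV missing columns: {missing}")
    counts: dict[str, np.ndarray] = {}
    for contig, grp in df.groupby("contig", sort=True):
        contig = str(contig)
        if contig_lengths is not None:
            if contig not in contig_lengths:
                raise ValueError(f"contig {contig} absent from manifest")
            length = contig_lengths[contig]
        else:
            length = int(grp["pos"].max()) + 1
        arr = np.zeros((length, 4), dtype=np.int64)
        pos = grp["pos"].to_numpy(dtype=np.int64)
        if (pos < 0).any() or (pos >= length).any():
            raise ValueError(f"contig {contig}: position outside [0, {length})")
        arr[pos] = grp[["A", "C", "G", "T"]].to_numpy(dtype=np.int64)
        counts[contig] = arr
    if contig_lengths is not None:
        for contig, length in contig_lengths.items():
            counts.setdefault(contig, np.zeros((length, 4), dtype=np.int64))
    return AlleleCounts(sample_id, counts)


def write_allele_counts_tsv(
    counts: AlleleCounts, dest: str | Path | IO[str]
) -> None:
    """Write allele counts as TSV; zero-depth positions are omitted."""
    frames = []
    for contig in counts.contigs:
        arr = counts.counts[contig]
        nz = np.flatnonzero(arr.sum(axis=1) > 0)
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "pos": nz,
                    "A": arr[nz, 0],
                    "C": arr[nz, 1],
                    "G": arr[nz, 2],
                    "T": arr[nz, 3],
                }
            )
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["contig", "pos", "A", "C", "G", "T"])
    )
    out.to_csv(dest, sep="\t", index=False)


def allele_counts_from_bam(
    bam_path: str | Path,
    sample_id: str,
    contig_lengths: Mapping[str, int],
    *,
    min_base_quality: int = 0,
) -> AlleleCounts:
    """Extract per-position allele counts from a BAM/SAM pileup via pysam.

    Deletions, reference skips and N bases never enter the counts, so depth
    is always the sum of the four base counts.
    """
    import pysam

    arrays = {
        contig: np.zeros((length, 4), dtype=np.int64)
        for contig, length in contig_lengths.items()
    }
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for contig in bam.references:
            if contig not in arrays:
                raise ValueError(
                    f"contig {contig} absent from the reference manifest"
                )
        for contig in arrays:
            if contig not in bam.references:
                continue  # no reads on this contig; counts stay zero
            cov = bam.count_coverage(
                contig=contig, quality_threshold=min_base_quality
            )
            for base_idx in range(4):
                arrays[contig][:, base_idx] = cov[base_idx]
    return AlleleCounts(sample_id, arrays, contig_lengths)


def shared_mask(
    a: AlleleCounts, b: AlleleCounts, cfg: StrainConfig | None = None
) -> SharedMask:
    """Positions "shared" between two samples.

    A contig qualifies iff >= ``contig_frac`` of its positions reach
    ``min_cov`` depth in *a* and, independently, in *b*.  A position is
    shared iff its contig qualifies in both and the position itself reaches
    ``min_cov`` in both.
    """
    cfg = cfg or StrainConfig()
    if a.contigs != b.contigs:
        raise ValueError(
            f"contig sets differ: {a.contigs} vs {b.contigs}"
        )
    masks: dict[str, np.ndarray] = {}
    shared = 0
    core = 0
    for contig in a.contigs:
        arr_a, arr_b = a.counts[contig], b.counts[contig]
        if arr_a.shape[0] != arr_b.shape[0]:
            raise ValueError(
                f"contig {contig}: length mismatch "
                f"{arr_a.shape[0]} vs {arr_b.shape[0]}"
            )
        core += arr_a.shape[0]
        depth_a = arr_a.sum(axis=1)
        depth_b = arr_b.sum(axis=1)
        ok_a = depth_a >= cfg.min_cov
        ok_b = depth_b >= cfg.min_cov
        if ok_a.mean() >= cfg.contig_frac and ok_b.mean() >= cfg.contig_frac:
            mask = ok_a & ok_b
        else:
            mask = np.zeros(arr_a.shape[0], dtype=bool)
        masks[contig] = mask
        shared += int(mask.sum())
    return SharedMask(masks=masks, shared_length=shared, core_length=core)


def count_exclusive_snvs(
    a: AlleleCounts,
    b: AlleleCounts,
    mask: SharedMask,
    cfg: StrainConfig | None = None,
) -> int:
    """Count a-exclusive SNVs over the shared positions.

    A position counts iff some base reaches >= ``major_freq`` frequency in
    *a* with >= ``major_min_reads`` supporting reads while its frequency in
    *b* stays below ``absent_freq``.  Positions where two bases tie at
    exactly 50% in *a* are ambiguous-majority and skipped.
    """
    cfg = cfg or StrainConfig()
    total = 0
    for contig in a.contigs:
        m = mask.masks[contig]
        if not m.any():
            continue
        arr_a = a.counts[contig][m].astype(float)
        arr_b = b.counts[contig][m].astype(float)
        depth_a = arr_a.sum(axis=1)
        depth_b = arr_b.sum(axis=1)
        # Masked positions always have depth >= min_cov >= 1 in both.
        freq_a = arr_a / depth_a[:, None]
        freq_b = arr_b / depth_b[:, None]
        majority = (freq_a >= cfg.major_freq) & (
            a.counts[contig][m] >= cfg.major_min_reads
        )
        ambiguous = majority.sum(axis=1) > 1
        exclusive = majority & (freq_b < cfg.absent_freq)
        total += int((exclusive.any(axis=1) & ~ambiguous).sum())
    return total


def aani_lowfreq(
    a: AlleleCounts, b: AlleleCounts, cfg: StrainConfig | None = None
) -> StrainDistance:
    """aANI-lowFreq distance a→b: a-exclusive SNVs per shared base.

    A pair with zero shared length yields an ineligible result (distance
    ``None``) rather than a division error.
    """
    cfg = cfg or StrainConfig()
    mask = shared_mask(a, b, cfg)
    snvs = (
        count_exclusive_snvs(a, b, mask, cfg) if mask.shared_length else 0
    )
    return StrainDistance(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        exclusive_snvs=snvs,
        shared_length=mask.shared_length,
        shared_core_fraction=mask.shared_fraction,
    )


def pair_eligibility(
    d: StrainDistance, cfg: StrainConfig | None = None
) -> bool:
    """A pair is eligible iff >= 50% of the core genome is shared."""
    cfg = cfg or StrainConfig()
    return d.shared_core_fraction >= cfg.min_shared_core


def calibrate_between_patient(
    distances: Sequence[float], cfg: StrainConfig | None = None
) -> np.ndarray | None:
    """Empirical between-patient calibration set for one species.

    Returns the sorted distances, or ``None`` when fewer than
    ``min_between_n`` are available (species uncalibratable).
    """
    cfg = cfg or StrainConfig()
    arr = np.sort(np.asarray(distances, dtype=float))
    if arr.size < cfg.min_between_n:
        return None
    return arr


def classify_interval(
    within_distance: float,
    calibration: np.ndarray | None,
    cfg: StrainConfig | None = None,
) -> bool | None:
    """Replacement call for one within-patient distance.

    Replacement iff the distance falls within the between-patient
    distribution, operationalized as >= its empirical
    ``replacement_quantile`` (default 5th percentile, an order statistic of
    the calibration set).  Uncalibrated species yield ``None`` (no call).
    """
    cfg = cfg or StrainConfig()
    if calibration is None:
        return None
    threshold = float(
        np.quantile(calibration, cfg.replacement_quantile, method="lower")
    )
    return bool(within_distance >= threshold)


@dataclass(frozen=True)
class IntervalCall:
    """Replacement call for one within-patient, within-species interval."""

    patient: str
    species: str
    sample_a: str
    sample_b: str
    day_a: float
    day_b: float
    distance: float | None
    replacement: bool | None
    spans_event: bool
    eligible: bool
    flags: tuple[str, ...] = ()


def make_interval_calls(
    distances: Mapping[str, Sequence[StrainDistance]],
    metadata: pd.DataFrame,
    events: pd.DataFrame,
    cfg: StrainConfig | None = None,
) -> list[IntervalCall]:
    """Classify consecutive same-patient sample intervals per species.

    ``distances`` maps species -> all pairwise StrainDistance records
    (both directions when available).  ``metadata`` needs columns
    sample_id, patient, day; ``events`` needs patient, day, event (only
    alloHSCT / relapse rows are considered).  For each species the
    between-patient distances of eligible pairs form the calibration set;
    consecutive within-patient intervals are then called on the maximum of
    the two directed distances, when both are present.
    """
    cfg = cfg or StrainConfig()
    meta = metadata.set_index("sample_id")
    relevant = events[events["event"].isin(["alloHSCT", "relapse"])]
    calls: list[IntervalCall] = []
    for species, dists in distances.items():
        eligible_dists = [
            d
            for d in dists
            if pair_eligibility(d, cfg) and d.aani_lowfreq is not None
        ]
        between = [
            d.aani_lowfreq
            for d in eligible_dists
            if meta.loc[d.sample_a, "patient"] != meta.loc[d.sample_b, "patient"]
        ]
        calibration = calibrate_between_patient(between, cfg)
        directed = {
            (d.sample_a, d.sample_b): d for d in eligible_dists
        }
        by_patient: dict[str, list[str]] = {}
        samples = sorted(
            {s for d in dists for s in (d.sample_a, d.sample_b)}
        )
        for s in samples:
            by_patient.setdefault(str(meta.loc[s, "patient"]), []).append(s)
        for patient, plist in sorted(by_patient.items()):
            plist = sorted(plist, key=lambda s: float(meta.loc[s, "day"]))
            for s1, s2 in zip(plist, plist[1:]):
                day1 = float(meta.loc[s1, "day"])
                day2 = float(meta.loc[s2, "day"])
                pair_dists = [
                    d.aani_lowfreq
                    for key in ((s1, s2), (s2, s1))
                    if (d := directed.get(key)) is not None
                ]
                flags = []
                if not pair_dists:
                    flags.append("ineligible-pair")
                    dist = None
                    repl = None
                else:
                    dist = max(pair_dists)
                    repl = classify_interval(dist, calibration, cfg)
                    if repl is None:
                        flags.append("uncalibrated-species")
                patient_events = relevant[
                    relevant["patient"].astype(str) == patient
                ]
                spans = bool(
                    (
                        (patient_events["day"] > day1)
                        & (patient_events["day"] <= day2)
                    ).any()
                )
                calls.append(
                    IntervalCall(
                        patient=patient,
                        species=species,
                        sample_a=s1,
                        sample_b=s2,
                        day_a=day1,
                        day_b=day2,
                        distance=dist,
                        replacement=repl,
                        spans_event=spans,
                        eligible=bool(pair_dists),
                        flags=tuple(flags),
                    )
                )
    return calls


def event_association(
    calls: Sequence[IntervalCall],
) -> tuple[np.ndarray, float]:
    """2x2 association of replacement calls with event-spanning intervals.

    Rows: replacement yes/no; columns: spans an alloHSCT/relapse event
    yes/no.  Returns the table and the two-sided Fisher exact p.
    """
    called = [c for c in calls if c.replacement is not None]
    if not called:
        raise ValueError("no classified intervals")
    table = np.zeros((2, 2), dtype=int)
    for c in called:
        i = 0 if c.replacement else 1
        j = 0 if c.spans_event else 1
        table[i, j] += 1
    return table, fisher_exact_2x2(table)
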