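"""Deterministic per-sample scoring formulas.

This module implements the closed-form scores used throughout the pipeline:

* the weighted genome instability index (wGII) of an absolute copy-number
  segment profile — the mean, over chromosomes, of the fraction of each
  chromosome's covered length whose copy number differs from the sample's
  baseline, so that every chromosome contributes equally regardless of size;
* inference of the per-sample baseline copy number as the length-weighted
  modal integer copy number;
* the RNA in-situ hybridization H-score (0-400);
* the five-way N-glycan composition classification
  (oligomannose / sialylated / fucosylated / fuco-sialylated / neutral).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError, MissingChromosomeError, ValidationError

#: Default chromosome set for wGII: autosomes only, so mixed-sex cohorts are
#: scored on a common denominator.
AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

SEGMENT_COLUMNS = ("chrom", "start", "end", "copy_number")


def _normalize_chrom(c) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass
class SegmentProfile:
    """Absolute copy-number segments of one sample.

    ``segments`` holds one row per segment with columns ``chrom``, ``start``,
    ``end`` (1-based inclusive base-pair coordinates) and integer
    ``copy_number``. Segments within a chromosome must be non-overlapping;
    they are sorted on construction.
    """

    sample_id: str
    segments: pd.DataFrame

    def __post_init__(self):
        seg = self.segments
        missing = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
        if missing:
            raise ValidationError(f"segment table missing columns {missing}")
        if len(seg) == 0:
            raise EmptyInputError(f"sample {self.sample_id!r}: empty segment profile")
        seg = seg.copy()
        seg["chrom"] = seg["chrom"].map(_normalize_chrom)
        for col in ("start", "end", "copy_number"):
            vals = seg[col].to_numpy()
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                raise ValidationError(f"sample {self.sample_id!r}: non-integer {col}")
            seg[col] = vals.astype(np.int64)
        if (seg["copy_number"] < 0).any():
            raise ValidationError(f"sample {self.sample_id!r}: negative copy number")
        if (seg["end"] < seg["start"]).any():
            raise ValidationError(f"sample {self.sample_id!r}: segment with end < start")
        seg = seg.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        for chrom, grp in seg.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(starts[1:] <= ends[:-1]):
                raise ValidationError(
                    f"sample {self.sample_id!r}: overlapping segments on chromosome {chrom}"
                )
        self.segments = seg

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.segments["chrom"]))

    def lengths(self) -> np.ndarray:
        seg = self.segments
        return (seg["end"] - seg["start"] + 1).to_numpy()


@dataclass
class WGIIResult:
    """wGII of one sample together with its per-chromosome aberrant fractions."""

    sample_id: str
    baseline: int
    per_chromosome_fraction: dict[str, float]
    wgii: float


def infer_baseline(profile: SegmentProfile) -> int:
    """Length-weighted modal integer copy number of a profile.

    Ties are broken toward the smaller copy number. This is the reference
    state against which aberration is defined; callers may override it with
    a known (rounded) ploidy.
    """
    seg = profile.segments
    weights = profile.lengths().astype(np.float64)
    totals = pd.Series(weights).groupby(seg["copy_number"].to_numpy()).sum()
    best = totals.max()
    # groupby sorts keys ascending, idxmax returns the first (smallest) maximizer
    return int(totals[totals == best].index.min())


def compute_wgii(
    profile: SegmentProfile,
    baseline: int | None = None,
    chromosomes: list[str] | None = None,
) -> WGIIResult:
    """Weighted genome instability index of one sample.

    Per chromosome, the aberrant fraction is the summed length of segments
    whose copy number differs from ``baseline``, divided by the chromosome's
    total covered segment length; the wGII is the unweighted mean of these
    fractions over ``chromosomes`` (default: autosomes present in the
    profile), giving each chromosome equal contribution.
    """
    if baseline is None:
        baseline = infer_baseline(profile)
    baseline = int(baseline)
    present = set(profile.chromosomes)
    if chromosomes is None:
        chromosomes = [c for c in profile.chromosomes if c in AUTOSOMES] or profile.chromosomes
    else:
        chromosomes = [_normalize_chrom(c) for c in chromosomes]
    seg = profile.segments
    lengths = profile.lengths().astype(np.float64)
    aberrant = (seg["copy_number"].to_numpy() != baseline)
    fractions: dict[str, float] = {}
    chrom_arr = seg["chrom"].to_numpy()
    for chrom in chromosomes:
        if chrom not in present:
            raise MissingChromosomeError(
                f"sample {profile.sample_id!r}: chromosome {chrom!r} has no segments"
            )
        mask = chrom_arr == chrom
        total = lengths[mask].sum()
        fractions[chrom] = float(lengths[mask & aberrant].sum() / total)
    return WGIIResult(
        sample_id=profile.sample_id,
        baseline=baseline,
        per_chromosome_fraction=fractions,
        wgii=float(np.mean(list(fractions.values()))),
    )


def wgii_table(
    profiles: list[SegmentProfile],
    baseline: int | None = None,
    chromosomes: list[str] | None = None,
) -> pd.DataFrame:
    """wGII for a cohort; one row per sample with columns baseline and wgii."""
    rows = []
    for p in profiles:
        r = compute_wgii(p, baseline=baseline, chromosomes=chromosomes)
        rows.append({"sample_id": r.sample_id, "baseline": r.baseline, "wgii": r.wgii})
    return pd.DataFrame(rows).set_index("sample_id")


def h_score(percentages) -> float:
    """RNA-ISH H-score: sum of bin percentages weighted by bin score 0-4.

    ``percentages`` are the five percentages of cells scored 0,1,2,3,4; they
    must sum to 100. The result lies in [0, 400].
    """
    p = np.asarray(percentages, dtype=np.float64)
    if p.shape != (5,):
        raise ValidationError("h_score expects exactly five percentages")
    if (p < 0).any() or (p > 100).any():
        raise ValidationError("percentages must lie in [0, 100]")
    if abs(p.sum() - 100.0) > 1e-6:
        raise ValidationError(f"percentages must sum to 100, got {p.sum()!r}")
    return float(np.dot(p, np.arange(5)))


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide counts of one N-glycan."""

    hexnac: int = 0
    hex: int = 0
    fuc: int = 0
    neuac: int = 0
    neugc: int = 0

    def __post_init__(self):
        counts = (self.hexnac, self.hex, self.fuc, self.neuac, self.neugc)
        if any(c < 0 for c in counts):
            raise ValidationError("monosaccharide counts must be non-negative")
        if all(c == 0 for c in counts):
            raise ValidationError("empty glycan composition")


GLYCOFORM_CATEGORIES = (
    "oligomannose",
    "sialylated",
    "fucosylated",
    "fuco-sialylated",
    "neutral",
)


def classify_glycoform(g: GlycanComposition, oligomannose_min_hex: int = 5) -> str:
    """Assign a glycan composition to one of five glycoform categories.

    Sialic acid content is NeuAc + NeuGc. Precedence: fuco-sialylated
    (both fucose and sialic acid) before the single-feature classes;
    oligomannose requires the bare HexNAc(2)Hex(>=``oligomannose_min_hex``)
    core with neither fucose nor sialic acid; everything else is neutral.
    """
    sialic = g.neuac + g.neugc
    if g.fuc > 0 and sialic > 0:
        return "fuco-sialylated"
    if sialic > 0:
        return "sialylated"
    if g.fuc > 0:
        return "fucosylated"
    if g.hexnac == 2 and g.hex >= oligomannose_min_hex:
        return "oligomannose"
    return "neutral"
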