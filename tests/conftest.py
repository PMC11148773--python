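"""Shared fixtures and independent oracles used across the test suite."""

import numpy as np
import pandas as pd
import pytest

from gicoreg.scores import SegmentProfile


def brute_force_wgii(profile: SegmentProfile, baseline: int, chromosomes=None) -> float:
    """Per-base-pair recomputation of wGII, independent of the implementation.

    Materializes every covered base of every chromosome and tallies bases
    whose copy number differs from the baseline; the per-chromosome fraction
    uses covered bases as denominator.
    """
    seg = profile.segments
    chroms = chromosomes if chromosomes is not None else list(dict.fromkeys(seg["chrom"]))
    fractions = []
    for chrom in chroms:
        sub = seg[seg["chrom"] == chrom]
        length = int(sub["end"].max()) + 1
        cn = np.full(length, -1, dtype=np.int64)  # -1 = uncovered
        for _, row in sub.iterrows():
            cn[int(row["start"]) : int(row["end"]) + 1] = int(row["copy_number"])
        covered = cn >= 0
        fractions.append(((cn != baseline) & covered).sum() / covered.sum())
    return float(np.mean(fractions))


def brute_force_baseline(profile: SegmentProfile) -> int:
    """Per-base modal copy number; ties toward the smaller copy number."""
    seg = profile.segments
    tallies: dict[int, int] = {}
    for _, row in seg.iterrows():
        cn = int(row["copy_number"])
        tallies[cn] = tallies.get(cn, 0) + int(row["end"]) - int(row["start"]) + 1
    best = max(tallies.values())
    return min(cn for cn, t in tallies.items() if t == best)


def random_profile(rng: np.random.Generator, n_chroms=3, max_len=2000, with_gaps=False):
    """A random valid segment profile over small chromosomes."""
    rows = []
    for c in range(1, n_chroms + 1):
        pos = 1
        length = int(rng.integers(200, max_len))
        while pos < length:
            seg_len = int(rng.integers(20, 300))
            end = min(pos + seg_len - 1, length)
            rows.append(
                {
                    "chrom": str(c),
                    "start": pos,
                    "end": end,
                    "copy_number": int(rng.integers(0, 6)),
                }
            )
            pos = end + 1
            if with_gaps and rng.random() < 0.3:
                pos += int(rng.integers(1, 50))
    return SegmentProfile(sample_id="rand", segments=pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(20240503)


@pytest.fixture
def toy_profile():
    """Two chromosomes of 100 bp with aberrant fractions 0.4 and 0.5."""
    seg = pd.DataFrame(
        {
            "chrom": ["1", "1", "2", "2"],
            "start": [1, 41, 1, 51],
            "end": [40, 100, 50, 100],
            "copy_number": [3, 2, 4, 2],
        }
    )
    return SegmentProfile(sample_id="toy", segments=seg)
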