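"""Readers and writers for the pipeline's TSV/JSON dialects.

All tables are tab-separated text. Segment coordinates are 1-based
inclusive (SEG-like); a leading ``chr`` prefix on chromosome names is
tolerated and stripped. Expression matrices carry the feature id in the
first column and one column per sample; empty cells or ``NA`` mean missing.
Writers and readers round-trip losslessly (floats are written with
shortest-round-trip repr).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .scores import SegmentProfile
from .simulate import GroundTruth

SEGMENT_HEADER = ["sample", "chrom", "start", "end", "copy_number"]


def write_segments(profiles: list[SegmentProfile], path) -> None:
    frames = []
    for p in profiles:
        df = p.segments.copy()
        df.insert(0, "sample", p.sample_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[SegmentProfile]:
    """Parse a SEG-like TSV into per-sample validated profiles.

    Overlapping segments or end < start are rejected with the offending
    1-based file line number.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed segment file {path}: {exc}") from exc
    missing = [c for c in SEGMENT_HEADER if c not in df.columns]
    if missing:
        raise ParseError(f"segment file {path} missing columns {missing}")
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1
    bad = df[df["end"] < df["start"]]
    if len(bad):
        raise ParseError("segment with end < start", line=int(bad["_line"].iloc[0]))
    profiles = []
    for sid, grp in df.groupby("sample", sort=True):
        g = grp.sort_values(["chrom", "start"], kind="stable")
        for _, chrom_grp in g.groupby("chrom", sort=False):
            starts = chrom_grp["start"].to_numpy()
            ends = chrom_grp["end"].to_numpy()
            lines = chrom_grp["_line"].to_numpy()
            overlap = np.flatnonzero(starts[1:] <= ends[:-1])
            if len(overlap):
                raise ParseError(
                    f"overlapping segments for sample {sid!r}",
                    line=int(lines[overlap[0] + 1]),
                )
        profiles.append(
            SegmentProfile(sample_id=str(sid), segments=g[["chrom", "start", "end", "copy_number"]])
        )
    return profiles


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id", na_rep="")


def read_matrix(path) -> pd.DataFrame:
    """Feature x sample matrix from TSV; empty cells and NA become missing."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed matrix file {path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate feature id {dup!r} in {path}")
    return df.astype(np.float64)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample_id")


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", float_precision="round_trip")


def write_ks_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_ks_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"kinase": str, "substrate": str, "residue": str})


def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "true_wgii": {k: float(v) for k, v in truth.true_wgii.items()},
        "true_group": {k: str(v) for k, v in truth.true_group.items()},
        "planted_pairs": sorted(truth.planted_pairs),
        "true_effects": {k: list(v) for k, v in sorted(truth.true_effects.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        true_wgii=pd.Series(payload["true_wgii"], dtype=np.float64),
        true_group=pd.Series(payload["true_group"]),
        planted_pairs=set(payload["planted_pairs"]),
        true_effects={k: tuple(v) for k, v in payload["true_effects"].items()},
    )


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
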