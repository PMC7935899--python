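"""Text-format round-tripping: bedGraph, tidy TSV, reports, manifests."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .crosslinks import CrosslinkTrack
from .profiles import NormalizedProfile
from .substrate import Substrate

__all__ = [
    "write_bedgraph",
    "read_bedgraph",
    "tracks_to_tidy",
    "profile_to_tidy",
    "write_manifest",
]


def write_bedgraph(
    track: CrosslinkTrack | NormalizedProfile, path: str | Path
) -> None:
    """Write per-position values as bedGraph (0-based, half-open).

    Consecutive equal non-zero values are merged into one interval, the
    usual bedGraph run-length convention.
    """
    values = track.counts if isinstance(track, CrosslinkTrack) else track.values
    name = track.reference_name
    with open(path, "w") as fh:
        start = None
        current = None
        for i, v in enumerate(values):
            if v != current:
                if current not in (None, 0):
                    fh.write(f"{name}\t{start}\t{i}\t{_fmt(current)}\n")
                start, current = i, v
        if current not in (None, 0):
            fh.write(f"{name}\t{start}\t{len(values)}\t{_fmt(current)}\n")


def _fmt(v) -> str:
    f = float(v)
    return str(int(f)) if f.is_integer() else repr(f)


def read_bedgraph(path: str | Path, reference_length: int) -> CrosslinkTrack:
    """Rebuild a crosslink track from a single-reference bedGraph."""
    counts = np.zeros(reference_length, dtype=np.int64)
    name = None
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            ref, a, b, v = line.split("\t")
            if name is None:
                name = ref
            elif ref != name:
                raise ValueError("bedGraph contains multiple references")
            counts[int(a) : int(b)] = int(float(v))
    if name is None:
        raise ValueError("empty bedGraph")
    return CrosslinkTrack(name, counts)


def tracks_to_tidy(
    tracks: Mapping[str, CrosslinkTrack], substrate: Substrate | None = None
) -> pd.DataFrame:
    """Tidy per-position table with absolute and landmark-relative coordinates."""
    frames = []
    for name, track in tracks.items():
        nz = np.nonzero(track.counts)[0]
        df = pd.DataFrame(
            {"reference": name, "position": nz, "count": track.counts[nz]}
        )
        if substrate is not None and name == substrate.name:
            df["rel_brA"] = df.position - substrate.brA
            df["rel_ss3"] = df.position - substrate.ss3
        else:
            df["rel_brA"] = np.nan
            df["rel_ss3"] = np.nan
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["reference", "position", "count", "rel_brA", "rel_ss3"]
    )


def profile_to_tidy(
    profile: NormalizedProfile, substrate: Substrate | None = None
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "reference": profile.reference_name,
            "position": np.arange(len(profile)),
            "value": profile.values,
        }
    )
    if substrate is not None and profile.reference_name == substrate.name:
        df["rel_brA"] = df.position - substrate.brA
        df["rel_ss3"] = df.position - substrate.ss3
    return df


def write_manifest(config: dict, path: str | Path) -> None:
    """Echo the fully resolved run configuration next to its outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
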