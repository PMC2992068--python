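"""Writers for track and profile artifacts (TSV, BedGraph)."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def track_to_tsv(seq_id: str, values: np.ndarray, path: str | Path) -> None:
    """3-column TSV: seq_id, 1-based position, value (6 significant digits)."""
    with open(path, "w") as fh:
        fh.write("seq_id\tposition\tvalue\n")
        for i, v in enumerate(values):
            fh.write(f"{seq_id}\t{i + 1}\t{v:.6g}\n")


def track_to_bedgraph(seq_id: str, values: np.ndarray, path: str | Path) -> None:
    """BedGraph with runs of equal value collapsed."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{seq_id}"\n')
        start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or f"{values[i]:.6g}" != f"{values[start]:.6g}":
                fh.write(f"{seq_id}\t{start}\t{i}\t{values[start]:.6g}\n")
                start = i
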