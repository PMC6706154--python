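"""Segmentation validation (DICE) and consolidated tabular export.

DICE = 2|X ∩ Y| / (|X| + |Y|) scores spatial overlap between an
automated mask and a reference mask; values above 0.7 are conventionally
taken as effective overlap.  Pipeline outputs are consolidated into an
xlsx workbook with bit-identical CSV mirrors, keyed by (experiment,
fish) so re-running an analysis updates rows idempotently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ros import GeometryError

log = logging.getLogger("fintrack")

EFFECTIVE_DICE = 0.7


class ExportError(ValueError):
    """Nothing to export or the export target is unusable."""


@dataclass
class DiceResult:
    """Per-frame DICE values for one mask class."""

    label: str
    values: np.ndarray
    below_threshold: list[int]

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if self.values.size > 1 else 0.0


def dice(reference: np.ndarray, test: np.ndarray) -> float:
    """DICE similarity coefficient of two binary masks.

    Two empty masks agree perfectly on absence and score 1 (with a
    logged warning, since that usually signals an upstream problem).
    """
    reference = np.asarray(reference).astype(bool)
    test = np.asarray(test).astype(bool)
    if reference.shape != test.shape:
        raise GeometryError(
            f"mask shapes differ: {reference.shape} vs {test.shape}")
    size = int(reference.sum()) + int(test.sum())
    if size == 0:
        log.warning("dice: both masks empty, defining overlap as 1")
        return 1.0
    return 2.0 * int((reference & test).sum()) / size


def validate_sequence(
    references: Sequence[np.ndarray],
    tests: Sequence[np.ndarray],
    label: str = "",
    threshold: float = EFFECTIVE_DICE,
) -> DiceResult:
    """Frame-wise DICE over two mask sequences, flagging weak frames."""
    if len(references) != len(tests):
        raise GeometryError(
            f"{len(references)} reference vs {len(tests)} test masks")
    values = np.array([dice(r, t) for r, t in zip(references, tests)])
    below = [i for i, v in enumerate(values) if v < threshold]
    if below:
        log.warning("%s: %d/%d frames below DICE %.2f",
                    label or "masks", len(below), len(values), threshold)
    return DiceResult(label=label, values=values, below_threshold=below)


#: canonical sheet order in the consolidated workbook
SHEETS = ("ctf", "tracks", "metrics", "recruitment", "summary", "params")


def export_workbook(
    tables: Mapping[str, pd.DataFrame],
    xlsx_path: str | Path,
    csv_dir: str | Path | None = None,
    keys: Sequence[str] = ("experiment", "fish"),
) -> dict[str, Path]:
    """Write pipeline tables to a workbook plus CSV mirrors, append-safely.

    For each table, rows whose key columns match already-exported rows
    are replaced; everything else is preserved, so adding one fish to an
    analysed experiment appends exactly its rows.  CSV mirrors are the
    canonical output (sorted, full precision); the workbook is a
    convenience view.  Re-export of unchanged inputs is byte-identical.
    """
    tables = {k: v for k, v in tables.items() if v is not None and not v.empty}
    if not tables:
        raise ExportError("no non-empty tables to export")
    xlsx_path = Path(xlsx_path)
    csv_dir = Path(csv_dir) if csv_dir is not None else xlsx_path.parent
    csv_dir.mkdir(parents=True, exist_ok=True)
    xlsx_path.parent.mkdir(parents=True, exist_ok=True)

    merged: dict[str, pd.DataFrame] = {}
    for name, df in tables.items():
        df = df.copy()
        csv_path = csv_dir / f"{name}.csv"
        key_cols = [k for k in keys if k in df.columns]
        if csv_path.is_file() and key_cols:
            old = pd.read_csv(csv_path)
            old_keys = set(map(tuple, old[key_cols].astype(str).to_numpy()))
            new_keys = set(map(tuple, df[key_cols].astype(str).to_numpy()))
            keep = old[~old[key_cols].astype(str).apply(tuple, axis=1)
                       .isin(new_keys)]
            df = pd.concat([keep, df], ignore_index=True)
        sort_cols = [c for c in df.columns
                     if c in (*keys, "frame", "mpi", "track_id", "metric",
                              "time_domain", "space_domain")]
        if sort_cols:
            df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
        merged[name] = df

    paths: dict[str, Path] = {}
    for name, df in merged.items():
        csv_path = csv_dir / f"{name}.csv"
        csv_path.write_text(df.to_csv(index=False))
        paths[name] = csv_path
    with pd.ExcelWriter(xlsx_path, engine="openpyxl") as writer:
        for name in SHEETS:
            if name in merged:
                merged[name].to_excel(writer, sheet_name=name, index=False)
        for name in merged:
            if name not in SHEETS:
                merged[name].to_excel(writer, sheet_name=name[:31], index=False)
    paths["workbook"] = xlsx_path
    return paths


def plot_tracks(trackset, path: str | Path, s_o=None) -> Path:
    """Simple xy overview of all tracks (static image export)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for tr in trackset:
        pos = tr.positions
        ax.plot(pos[:, 0], pos[:, 1], lw=0.8)
        ax.plot(pos[-1, 0], pos[-1, 1], "k.", ms=3)
    if s_o is not None:
        ax.plot(s_o[0], s_o[1], "r*", ms=12, label="S_o")
        ax.legend()
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.invert_yaxis()
    ax.set_aspect("equal")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
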