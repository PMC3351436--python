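"""Readers, writers and domain containers shared by every analysis stage.

All modules speak the same residue-indexing convention: residues carry their
author-assigned integer numbers (which need not start at 1 and may have gaps),
and no operation ever silently renumbers from zero.  Coordinates are in
angstroms, chemical shifts in ppm, relaxation rates in s^-1.

Missing observables (overlapped or exchange-broadened NMR peaks, absent
R1rho columns, ...) are represented as NaN and are never collapsed to zero.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("allodyn")

__all__ = [
    "Trajectory",
    "ResidueRange",
    "PeakTable",
    "RelaxationDataset",
    "TrajectoryFormatError",
    "TableFormatError",
    "read_trajectory",
    "read_peak_table",
    "read_relaxation_table",
    "write_peak_table",
    "write_relaxation_table",
    "write_matrix",
    "read_matrix",
    "write_report",
    "read_report",
]

REPORT_SCHEMA_VERSION = "1.0"


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory file cannot be parsed into a valid Trajectory."""


class TableFormatError(ValueError):
    """Raised when a TSV peak/relaxation table violates its contract."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueRange:
    """Inclusive author-numbered residue window, e.g. 25:155 for the folded core."""

    first: int
    last: int

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError(f"invalid residue range {self.first}:{self.last}")

    def contains(self, ids: np.ndarray) -> np.ndarray:
        ids = np.asarray(ids)
        return (ids >= self.first) & (ids <= self.last)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.first}:{self.last}"

    @classmethod
    def parse(cls, text: str) -> "ResidueRange":
        """Parse 'first:last' (also accepts 'first-last')."""
        sep = ":" if ":" in text else "-"
        first, last = (int(p) for p in text.split(sep, 1))
        return cls(first, last)


@dataclass
class Trajectory:
    """One representative point per residue per frame.

    coords has shape (n_frames, n_residues, 3) in angstroms; residue_ids are
    the author numbers in the same column order for every frame.
    """

    coords: np.ndarray
    residue_ids: np.ndarray
    atom_selection: str = "CA"
    frame_times: np.ndarray | None = None  # ns, optional

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, residues, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.coords.shape[1] != self.residue_ids.size:
            raise ValueError("coords/residue_ids shape mismatch")
        if np.unique(self.residue_ids).size != self.residue_ids.size:
            raise ValueError("duplicate residue ids in trajectory")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def select_range(self, rng: ResidueRange) -> "Trajectory":
        """Restrict to residues within `rng`; errors if the window is empty."""
        mask = rng.contains(self.residue_ids)
        if not mask.any():
            raise ValueError(f"no residues of {rng} present in trajectory")
        return Trajectory(
            self.coords[:, mask, :],
            self.residue_ids[mask],
            atom_selection=self.atom_selection,
            frame_times=self.frame_times,
        )


@dataclass
class PeakTable:
    """Per-residue amide peak list for one 2-D spectrum.

    Columns: residue (int), dH (ppm), dN (ppm), intensity (a.u., >=0 or NaN),
    sidechain (bool; Asn/Gln/Arg side-chain N-H peaks vs backbone amides).
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    REQUIRED = ("residue", "dH", "dN", "intensity")

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise TableFormatError(f"peak table missing column '{col}'")
        if "sidechain" not in df.columns:
            df["sidechain"] = False
        df["sidechain"] = df["sidechain"].astype(bool)
        df["residue"] = df["residue"].astype(int)
        dup = df.duplicated(subset=["residue", "sidechain"])
        if dup.any():
            bad = sorted(df.loc[dup, "residue"].unique().tolist())
            raise TableFormatError(f"duplicate residue id(s) in peak table: {bad}")
        inten = df["intensity"].to_numpy(dtype=float)
        if np.any(inten[np.isfinite(inten)] < 0):
            raise TableFormatError("negative peak intensity")
        self.data = df.reset_index(drop=True)

    @property
    def backbone(self) -> pd.DataFrame:
        return self.data[~self.data["sidechain"]]

    @property
    def sidechains(self) -> pd.DataFrame:
        return self.data[self.data["sidechain"]]


@dataclass
class RelaxationDataset:
    """Per-residue 15N relaxation rates at a single static field.

    Columns: residue, R1, R2, NOE, optional R1rho and per-quantity errors
    (R1_err, R2_err, NOE_err, R1rho_err).  field_mhz is the 1H resonance
    frequency of the spectrometer.
    """

    data: pd.DataFrame
    field_mhz: float
    meta: dict = field(default_factory=dict)

    REQUIRED = ("residue", "R1", "R2", "NOE")
    OPTIONAL = ("R1rho", "R1_err", "R2_err", "NOE_err", "R1rho_err")

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise TableFormatError(f"relaxation table missing column '{col}'")
        for col in self.OPTIONAL:
            if col not in df.columns:
                df[col] = np.nan
        df["residue"] = df["residue"].astype(int)
        if df["residue"].duplicated().any():
            bad = sorted(df.loc[df["residue"].duplicated(), "residue"].tolist())
            raise TableFormatError(f"duplicate residue id(s) in relaxation table: {bad}")
        if self.field_mhz <= 0:
            raise TableFormatError("spectrometer field must be positive")
        for rate in ("R1", "R2", "R1rho"):
            vals = df[rate].to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise TableFormatError(f"non-positive {rate} value")
        for err in ("R1_err", "R2_err", "NOE_err", "R1rho_err"):
            vals = df[err].to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise TableFormatError(f"non-positive error column {err}")
        self.data = df.reset_index(drop=True)

    def select_range(self, rng: ResidueRange) -> "RelaxationDataset":
        mask = rng.contains(self.data["residue"].to_numpy())
        if not mask.any():
            raise ValueError(f"no residues of {rng} in relaxation dataset")
        return RelaxationDataset(self.data[mask], self.field_mhz, dict(self.meta))


# ---------------------------------------------------------------------------
# trajectory readers
# ---------------------------------------------------------------------------

def _read_multimodel_pdb(path: str, selection: str) -> Trajectory:
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerant of hand-made fixtures
        structure = PDBParser(QUIET=True).get_structure("traj", path)
    models = list(structure)
    if not models:
        raise TrajectoryFormatError(f"{path}: no MODEL records found")

    def model_coords(model):
        out = {}
        for chain in model:
            for res in chain:
                if selection in res:
                    out[res.id[1]] = res[selection].get_coord().astype(float)
        return out

    per_model = [model_coords(m) for m in models]
    common = set(per_model[0])
    union = set()
    for d in per_model:
        common &= set(d)
        union |= set(d)
    dropped = sorted(union - common)
    if dropped:
        log.warning("dropping residues lacking atom %s in some frame: %s", selection, dropped)
    if not common:
        raise TrajectoryFormatError(f"{path}: no residue has atom '{selection}' in every model")
    ids = np.array(sorted(common), dtype=int)
    coords = np.array([[d[i] for i in ids] for d in per_model], dtype=float)
    return Trajectory(coords, ids, atom_selection=selection)


def _read_coord_table(path: str, selection: str) -> Trajectory:
    """Whitespace-separated 'frame residue x y z' rows, one per residue per frame."""
    frames: dict[int, dict[int, np.ndarray]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise TrajectoryFormatError(f"{path}:{lineno}: expected 'frame residue x y z'")
            try:
                fidx, rid = int(parts[0]), int(parts[1])
                xyz = np.array([float(p) for p in parts[2:]], dtype=float)
            except ValueError as exc:
                raise TrajectoryFormatError(f"{path}:{lineno}: {exc}") from None
            frames.setdefault(fidx, {})
            if rid in frames[fidx]:
                raise TrajectoryFormatError(
                    f"{path}:{lineno}: duplicate residue {rid} in frame {fidx}")
            frames[fidx][rid] = xyz
    if not frames:
        raise TrajectoryFormatError(f"{path}: empty coordinate table")
    order = sorted(frames)
    ids = sorted(frames[order[0]])
    for fidx in order:
        got = sorted(frames[fidx])
        if got != ids:
            missing = sorted(set(ids) ^ set(got))
            raise TrajectoryFormatError(
                f"{path}: frame {fidx} residue set differs (mismatch at {missing})")
    coords = np.array([[frames[f][r] for r in ids] for f in order], dtype=float)
    return Trajectory(coords, np.array(ids, dtype=int), atom_selection=selection)


def _read_binary_traj(path: str, topology: str, selection: str) -> Trajectory:
    try:
        import mdtraj
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise TrajectoryFormatError("dcd/xtc input requires the optional mdtraj reader") from exc
    t = mdtraj.load(path, top=topology)
    idx = t.topology.select(f"name {selection}")
    if idx.size == 0:
        raise TrajectoryFormatError(f"no atoms named '{selection}' in topology")
    ids = np.array([t.topology.atom(i).residue.resSeq for i in idx], dtype=int)
    coords = t.xyz[:, idx, :].astype(float) * 10.0  # nm -> angstrom
    times = t.time / 1000.0 if t.time is not None else None  # ps -> ns
    return Trajectory(coords, ids, atom_selection=selection, frame_times=times)


def read_trajectory(
    path: str,
    format: str = "auto",
    selection: str = "CA",
    topology: str | None = None,
) -> Trajectory:
    """Read a trajectory as one representative atom per residue.

    Supported formats: ``multi-model-pdb`` (MODEL/ENDMDL records),
    ``coord-table`` (whitespace 'frame residue x y z' rows), and ``dcd``/``xtc``
    (require ``topology``; read through mdtraj).  ``auto`` guesses from the
    file extension.
    """
    fmt = format.lower().replace("_", "-")
    if fmt == "auto":
        lower = path.lower()
        if lower.endswith(".pdb"):
            fmt = "multi-model-pdb"
        elif lower.endswith((".dcd", ".xtc")):
            fmt = lower.rsplit(".", 1)[-1]
        else:
            fmt = "coord-table"
    if fmt in ("multi-model-pdb", "pdb"):
        return _read_multimodel_pdb(path, selection)
    if fmt in ("coord-table", "table", "tsv"):
        return _read_coord_table(path, selection)
    if fmt in ("dcd", "xtc"):
        if topology is None:
            raise TrajectoryFormatError(f"{fmt} input requires a topology file")
        return _read_binary_traj(path, topology, selection)
    raise TrajectoryFormatError(f"unknown trajectory format '{format}'")


def write_coord_table(traj: Trajectory, path: str) -> None:
    """Write the plain-text coordinate-table dialect (round-trips with the reader)."""
    with open(path, "w") as fh:
        fh.write("# frame residue x y z (angstrom)\n")
        for f in range(traj.n_frames):
            for r, rid in enumerate(traj.residue_ids):
                x, y, z = traj.coords[f, r]
                fh.write(f"{f}\t{rid}\t{x:.10g}\t{y:.10g}\t{z:.10g}\n")


# ---------------------------------------------------------------------------
# TSV tables with '#' metadata lines
# ---------------------------------------------------------------------------

def _split_meta(path: str) -> tuple[dict, str]:
    """Pull '# key value' metadata lines off the top of a TSV file."""
    meta: dict = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].strip().split(None, 1)
                if len(parts) == 2:
                    meta[parts[0]] = parts[1]
                continue
            body_lines.append(line)
    return meta, "".join(body_lines)


def read_peak_table(path: str) -> PeakTable:
    """Read a TSV peak table with columns residue/dH/dN/intensity[/sidechain].

    Empty cells stay missing (NaN); duplicated residues and non-numeric
    shifts are format errors naming the offending row.
    """
    meta, body = _split_meta(path)
    try:
        df = pd.read_csv(io.StringIO(body), sep="\t")
    except Exception as exc:
        raise TableFormatError(f"{path}: cannot parse TSV ({exc})") from None
    for col in ("dH", "dN", "intensity"):
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
            if bad.any():
                row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
                raise TableFormatError(f"{path}: non-numeric {col} at data row {row}")
            df[col] = coerced
    try:
        return PeakTable(df, meta=meta)
    except TableFormatError as exc:
        raise TableFormatError(f"{path}: {exc}") from None


def write_peak_table(table: PeakTable, path: str) -> None:
    with open(path, "w") as fh:
        for k, v in table.meta.items():
            fh.write(f"# {k} {v}\n")
        table.data.to_csv(fh, sep="\t", index=False, na_rep="")


def read_relaxation_table(path: str) -> RelaxationDataset:
    """Read a relaxation TSV; the field comes from a '# field_MHz <value>' line."""
    meta, body = _split_meta(path)
    key = next((k for k in meta if k.lower() in ("field_mhz", "field")), None)
    if key is None:
        raise TableFormatError(f"{path}: missing '# field_MHz <value>' metadata line")
    field_mhz = float(meta[key])
    try:
        df = pd.read_csv(io.StringIO(body), sep="\t")
    except Exception as exc:
        raise TableFormatError(f"{path}: cannot parse TSV ({exc})") from None
    try:
        return RelaxationDataset(df, field_mhz=field_mhz, meta=meta)
    except TableFormatError as exc:
        raise TableFormatError(f"{path}: {exc}") from None


def write_relaxation_table(ds: RelaxationDataset, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# field_MHz {ds.field_mhz:g}\n")
        for k, v in ds.meta.items():
            if k.lower() not in ("field_mhz", "field"):
                fh.write(f"# {k} {v}\n")
        cols = [c for c in ds.data.columns
                if c in ds.REQUIRED + ds.OPTIONAL]
        ds.data[cols].to_csv(fh, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# matrices and reports
# ---------------------------------------------------------------------------

def write_matrix(values: np.ndarray, residue_ids: np.ndarray, path: str) -> None:
    """Residue-by-residue matrix as TSV with id row/column headers."""
    ids = np.asarray(residue_ids, dtype=int)
    values = np.asarray(values, dtype=float)
    if values.shape != (ids.size, ids.size):
        raise ValueError("matrix shape does not match residue id count")
    df = pd.DataFrame(values, index=ids, columns=ids)
    df.to_csv(path, sep="\t", index_label="residue", float_format="%.12g")


def read_matrix(path: str) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = df.index.to_numpy(dtype=int)
    cols = np.array([int(c) for c in df.columns], dtype=int)
    if not np.array_equal(ids, cols):
        raise TableFormatError(f"{path}: row/column residue headers differ")
    return df.to_numpy(dtype=float), ids


def write_report(report: dict, path: str) -> None:
    """JSON report with a schema version; keys sorted for byte-stable output."""
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **report}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
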