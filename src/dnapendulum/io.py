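"""File input/output: FASTA sequences, trajectory CSV, metadata sidecars.

Trajectories are written as plain CSV with a header row
(``t, phi_1_1 ... phi_1_n, phi_2_1 ... phi_2_n`` and optionally the
angular velocities) plus a JSON sidecar recording the sequence, viscosity
scale, forcing and solver settings, so a written run is self-describing.
Per-base parameter tables can be overridden from a YAML file for
sensitivity studies.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .dynamics import Trajectory
from .observables import ObservableSeries
from .parameters import BaseParameters
from .experiments import SweepResult

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_trajectory",
    "read_trajectory",
    "write_series",
    "write_sweep",
    "load_parameter_table",
]


def read_fasta(path: str | Path, record_id: str | None = None) -> str:
    """Read one sequence from a FASTA file.

    The first record is used by default; ``record_id`` selects a specific
    record from a multi-FASTA.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if record_id is None:
        return str(records[0].seq)
    for rec in records:
        if rec.id == record_id:
            return str(rec.seq)
    raise KeyError(f"record {record_id!r} not found in {path}")


def write_fasta(path: str | Path, seq: str, record_id: str = "synthetic") -> None:
    """Write a single-record FASTA file."""
    rec = SeqRecord(Seq(seq), id=record_id, description="")
    SeqIO.write([rec], str(path), "fasta")


def write_trajectory(
    traj: Trajectory, prefix: str | Path, include_velocities: bool = False
) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` (time series) and ``<prefix>.meta.json``.

    Returns the two paths written.
    """
    prefix = Path(prefix)
    n = traj.n
    cols: dict[str, np.ndarray] = {"t": traj.times}
    for j in (0, 1):
        for i in range(n):
            cols[f"phi_{j + 1}_{i + 1}"] = traj.phi[:, j, i]
    if include_velocities:
        for j in (0, 1):
            for i in range(n):
                cols[f"omega_{j + 1}_{i + 1}"] = traj.omega[:, j, i]
    csv_path = prefix.with_suffix(".csv")
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.17g")
    meta_path = prefix.with_suffix(".meta.json")
    meta = dict(traj.meta)
    meta["code_version"] = __version__
    meta["include_velocities"] = include_velocities
    meta_path.write_text(json.dumps(meta, indent=2))
    return csv_path, meta_path


def read_trajectory(prefix: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"), float_precision="round_trip")
    meta_path = prefix.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    phi_cols = [c for c in df.columns if c.startswith("phi_")]
    n = len(phi_cols) // 2
    m = len(df)
    phi = np.empty((m, 2, n))
    omega = np.zeros((m, 2, n))
    for j in (0, 1):
        for i in range(n):
            phi[:, j, i] = df[f"phi_{j + 1}_{i + 1}"].to_numpy()
            vcol = f"omega_{j + 1}_{i + 1}"
            if vcol in df.columns:
                omega[:, j, i] = df[vcol].to_numpy()
    return Trajectory(times=df["t"].to_numpy(), phi=phi, omega=omega, meta=meta)


def write_series(series: ObservableSeries, path: str | Path) -> Path:
    """Write an observable series as a two-column CSV."""
    path = Path(path)
    pd.DataFrame(
        {"t": series.times, series.label or "value": series.values}
    ).to_csv(path, index=False, float_format="%.17g")
    return path


def write_sweep(sweep: SweepResult, out_dir: str | Path) -> dict[str, Path]:
    """Write per-lambda series CSVs plus a summary metrics CSV.

    Returns a mapping of logical names to written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for lam, series in zip(sweep.lambdas, sweep.series):
        p = out_dir / f"mean_deviation_lambda_{lam:g}.csv"
        write_series(series, p)
        written[f"series_{lam:g}"] = p
    summary = out_dir / "sweep_summary.csv"
    sweep.to_frame().to_csv(summary, index=False)
    written["summary"] = summary
    meta = out_dir / "sweep_meta.json"
    meta.write_text(json.dumps({**sweep.meta, "code_version": __version__}, indent=2))
    written["meta"] = meta
    return written


def load_parameter_table(path: str | Path) -> dict[str, BaseParameters]:
    """Load a per-base parameter override table from YAML.

    Expected layout (SI units)::

        A: {inertia: 7.61e-44, lever: 5.8e-10, backbone_stiffness: 2.35e-18,
            pair_stiffness: 6.2e-2, dissipation: 4.25e-34}
        T: {...}
        ...

    All four bases must be present; the Watson-Crick pair-stiffness
    equality (A == T, G == C) is enforced.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or set(raw) != {"A", "C", "G", "T"}:
        raise ValueError("parameter table must define exactly the bases A, C, G, T")
    table = {
        base: BaseParameters(
            base=base,
            inertia=float(row["inertia"]),
            lever=float(row["lever"]),
            backbone_stiffness=float(row["backbone_stiffness"]),
            pair_stiffness=float(row["pair_stiffness"]),
            dissipation=float(row["dissipation"]),
        )
        for base, row in raw.items()
    }
    if table["A"].pair_stiffness != table["T"].pair_stiffness or (
        table["G"].pair_stiffness != table["C"].pair_stiffness
    ):
        raise ValueError("pair stiffness must be equal within each Watson-Crick pair")
    return table
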