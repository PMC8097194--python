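"""File formats: clone tables, likelihood surfaces, ABC posteriors.

Clone tables are long-format CSV/TSV (one row per observed clone) with
header columns ``mouse_id, time_days, clone_size``; extra columns are
preserved as metadata.  Surfaces and posteriors serialize as CSV plus a
JSON sidecar, and every run can emit a machine-readable provenance record
(config + package version + seed) for bit-identical re-runs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import REQUIRED_COLUMNS, CloneDataset
from .likelihood import GridSpec, LikelihoodSurface
from .smcabc import ABCPosterior, posterior_summaries

__all__ = [
    "read_clone_table",
    "write_clone_table",
    "write_truth_table",
    "read_truth_table",
    "write_pmf_table",
    "read_pmf_table",
    "write_surface",
    "read_surface",
    "write_posterior",
    "write_provenance",
]


def read_clone_table(path) -> CloneDataset:
    """Read a long-format clone table (CSV, or TSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    meta = {"source": str(path)}
    if extra:
        meta["extra_columns"] = {c: df[c].tolist() for c in extra}
        df = df[list(REQUIRED_COLUMNS)]
    try:
        return CloneDataset(df, meta)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_clone_table(data: CloneDataset, path) -> None:
    data.table.to_csv(path, index=False)


def write_truth_table(truth, path) -> None:
    """Ground-truth ledger CSV; %.17g keeps float64 values bit-exact."""
    truth.to_csv(path, index=False, float_format="%.17g")


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_pmf_table(pmfs, path) -> None:
    """Serialize clone-size PMFs to CSV (time_days, n, probability,
    conditioned), one row per (timepoint, size)."""
    rows = []
    for pmf in pmfs:
        t_days = pmf.time_weeks * 7.0
        for n, prob in enumerate(pmf.probabilities):
            rows.append((t_days, n, prob, pmf.conditioned))
    pd.DataFrame(
        rows, columns=["time_days", "n", "probability", "conditioned"]
    ).to_csv(path, index=False, float_format="%.17g")


def read_pmf_table(path):
    from .pmf import CloneSizePMF

    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for t_days, group in df.groupby("time_days", sort=True):
        group = group.sort_values("n")
        out.append(CloneSizePMF(
            time_weeks=float(t_days) / 7.0,
            probabilities=group["probability"].to_numpy(),
            conditioned=bool(group["conditioned"].iloc[0]),
        ))
    return out


def _check_writable(outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    probe.touch()
    probe.unlink()
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_surface(surface: LikelihoodSurface, outdir, stem: str = "surface") -> dict:
    """CSV of (r, rho, loglik) rows plus a JSON sidecar of summaries."""
    outdir = _check_writable(outdir)
    R, P = np.meshgrid(surface.r_nodes, surface.rho_nodes, indexing="ij")
    df = pd.DataFrame({
        "r": R.ravel(), "rho": P.ravel(), "loglik": surface.loglik.ravel(),
    })
    csv_path = outdir / f"{stem}.csv"
    df.to_csv(csv_path, index=False, float_format="%.17g")  # exact round trip
    r_hat, rho_hat = surface.argmax
    sidecar = {
        "argmax": {"r": r_hat, "rho": rho_hat},
        "max_loglik": surface.max_loglik,
        "intervals": _jsonable(surface.intervals(0.95)),
        "settings": _jsonable(surface.metadata),
    }
    json_path = outdir / f"{stem}.json"
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return {"csv": str(csv_path), "json": str(json_path)}


def read_surface(csv_path) -> LikelihoodSurface:
    df = pd.read_csv(csv_path, float_precision="round_trip")
    r_nodes = np.sort(df["r"].unique())
    rho_nodes = np.sort(df["rho"].unique())
    grid = df.pivot(index="r", columns="rho", values="loglik")
    grid = grid.loc[r_nodes, rho_nodes]
    return LikelihoodSurface(r_nodes, rho_nodes, grid.to_numpy())


def write_posterior(post: ABCPosterior, outdir, stem: str = "posterior") -> dict:
    """CSV of weighted particles per generation + JSON summary."""
    outdir = _check_writable(outdir)
    frames = []
    n_gens = len(post.generation_particles)
    for g, parts in enumerate(post.generation_particles, start=1):
        frames.append(pd.DataFrame({
            "r": parts[:, 0], "rho": parts[:, 1],
            "weight": (post.weights if g == n_gens
                       else np.full(len(parts), np.nan)),
            "generation": g,
        }))
    df = pd.concat(frames, ignore_index=True)
    csv_path = outdir / f"{stem}.csv"
    df.to_csv(csv_path, index=False, float_format="%.17g")
    summary = posterior_summaries(post)
    summary.pop("kde", None)
    sidecar = {
        "summaries": _jsonable(summary),
        "tolerances": _jsonable(post.tolerances),
        "acceptance_rates": _jsonable(post.acceptance_rates),
        "mean_distances": _jsonable(post.mean_distances),
        "metadata": _jsonable(post.metadata),
        "config": _jsonable(dataclasses.asdict(post.config)),
    }
    json_path = outdir / f"{stem}.json"
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return {"csv": str(csv_path), "json": str(json_path)}


def write_provenance(outdir, config: dict, seed: int, stem: str = "provenance") -> str:
    """Machine-readable record of what produced a result directory."""
    from . import __version__

    outdir = _check_writable(outdir)
    record = {
        "package": "spclone",
        "version": __version__,
        "seed": int(seed),
        "config": _jsonable(config),
    }
    path = Path(outdir) / f"{stem}.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return str(path)
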