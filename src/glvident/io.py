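"""Plain-text serialization: trajectory CSV, counts TSV, YAML sidecars, JSON.

Conventions
-----------
* Trajectories (absolute or compositional) are CSV with a leading ``time``
  column and one column per taxon; compositional files may carry an extra
  ``total_abundance`` column.
* Read counts are TSV with ``time`` plus one integer column per taxon.
* Parameters and generation metadata travel in a YAML sidecar so the tabular
  files stay self-contained and diff-able.  No binary formats anywhere.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import PosteriorSample, RecoverySummary
from .model import AbundanceTrajectory, CompositionTrajectory, GLVParameters
from .synthetic import NoiseModel, ObservedCounts

__all__ = [
    "taxon_names",
    "write_trajectory",
    "read_abundance_trajectory",
    "read_composition_trajectory",
    "write_counts",
    "read_counts",
    "write_parameters",
    "read_parameters",
    "posterior_to_dict",
    "recovery_to_frame",
]

_TOTAL_COL = "total_abundance"


def taxon_names(n: int) -> list:
    return [f"taxon_{i + 1}" for i in range(n)]


def write_trajectory(traj, path) -> None:
    """Write an abundance or composition trajectory as CSV."""
    path = Path(path)
    if isinstance(traj, AbundanceTrajectory):
        df = pd.DataFrame(traj.abundances, columns=taxon_names(traj.n_species))
    elif isinstance(traj, CompositionTrajectory):
        df = pd.DataFrame(traj.proportions, columns=taxon_names(traj.n_species))
        if traj.total_abundance is not None:
            df[_TOTAL_COL] = traj.total_abundance
    else:
        raise TypeError(f"cannot serialize {type(traj).__name__}")
    df.insert(0, "time", traj.times)
    df.to_csv(path, index=False)


def _read_frame(path):
    df = pd.read_csv(path, sep=None, engine="python")
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing 'time' column")
    return df


def read_abundance_trajectory(path, kind: str = "deterministic") -> AbundanceTrajectory:
    df = _read_frame(path)
    taxa = [c for c in df.columns if c not in ("time", _TOTAL_COL)]
    return AbundanceTrajectory(
        df["time"].to_numpy(), df[taxa].to_numpy(dtype=float), kind=kind
    )


def read_composition_trajectory(path) -> CompositionTrajectory:
    df = _read_frame(path)
    taxa = [c for c in df.columns if c not in ("time", _TOTAL_COL)]
    total = df[_TOTAL_COL].to_numpy() if _TOTAL_COL in df.columns else None
    return CompositionTrajectory(
        df["time"].to_numpy(), df[taxa].to_numpy(dtype=float), total_abundance=total
    )


def write_counts(counts: ObservedCounts, path) -> None:
    """TSV taxon-by-sample table (taxa as columns, samples as rows)."""
    df = pd.DataFrame(counts.counts, columns=taxon_names(counts.n_species))
    df.insert(0, "time", counts.times)
    df.to_csv(Path(path), sep="\t", index=False)


def read_counts(path, depth: int | None = None) -> ObservedCounts:
    df = pd.read_csv(path, sep="\t")
    taxa = [c for c in df.columns if c != "time"]
    counts = df[taxa].to_numpy(dtype=np.int64)
    if depth is None:
        depths = np.unique(counts.sum(axis=1))
        if depths.size != 1:
            raise ValueError(f"{path}: inconsistent per-sample depths {depths}")
        depth = int(depths[0])
    return ObservedCounts(df["time"].to_numpy(), counts, depth=depth)


def write_parameters(
    params: GLVParameters,
    path,
    noise: NoiseModel | None = None,
    metadata: dict | None = None,
) -> None:
    """YAML sidecar: gLV parameters plus optional noise settings/metadata."""
    doc = {
        "n_species": params.n_species,
        "r": params.r.tolist(),
        "B": params.B.tolist(),
    }
    if noise is not None:
        doc["noise"] = {
            "sigma": np.asarray(noise.sigma).tolist(),
            "dt": noise.dt,
            "V": noise.V,
            "seed": noise.seed,
        }
    if metadata:
        doc["metadata"] = metadata
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_parameters(path):
    """Read a YAML sidecar; returns (GLVParameters, NoiseModel | None, metadata)."""
    doc = yaml.safe_load(Path(path).read_text())
    params = GLVParameters(np.asarray(doc["r"]), np.asarray(doc["B"]))
    noise = None
    if "noise" in doc:
        nz = doc["noise"]
        noise = NoiseModel(
            sigma=np.asarray(nz["sigma"]), dt=nz["dt"], V=nz["V"], seed=nz.get("seed")
        )
    return params, noise, doc.get("metadata", {})


def posterior_to_dict(post: PosteriorSample) -> dict:
    """JSON-ready posterior: retained samples, logliks, diagnostics, config echo."""
    cfg = post.config
    return {
        "param_names": list(post.param_names),
        "samples": post.samples.tolist(),
        "logliks": post.logliks.tolist(),
        "acceptance_rate": post.acceptance_rate,
        "collapsed_proposals": post.collapsed,
        "assumed_N0": post.assumed_N0,
        "prior": {
            "lower": post.prior.lower.tolist(),
            "upper": post.prior.upper.tolist(),
            "reference": post.prior.reference.tolist(),
        },
        "config": {
            "iterations": cfg.iterations,
            "stages": cfg.stages,
            "particles": cfg.particles,
            "proposal_scale": cfg.proposal_scale,
            "adapt_start": cfg.adapt_start,
            "thin": cfg.thin,
            "dt": cfg.dt,
            "sigma": cfg.sigma,
            "seed": cfg.seed,
            "reduced": cfg.reduced,
        },
    }


def recovery_to_frame(summary: RecoverySummary) -> pd.DataFrame:
    """Recovery summary as a tidy table (parameter, truth, estimate, error)."""
    return pd.DataFrame(
        {
            "parameter": summary.param_names,
            "truth": summary.truth,
            "estimate_mean": summary.estimate_mean,
            "estimate_median": summary.estimate_median,
            "relative_error": summary.relative_error,
        }
    )
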