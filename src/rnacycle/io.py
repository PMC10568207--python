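"""On-disk formats and run configuration.

Count matrices travel as Matrix Market files with shared ``barcodes.tsv`` /
``features.tsv`` sidecars plus a ``cells.tsv`` metadata table (barcode,
phase in radians, labeling time in hours, sample), the layout standard
single-cell tooling expects.  Profiles and per-gene reports are plain TSV.
Every pipeline run drops a ``provenance.json`` snapshot (config, seed,
package version) next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from . import __version__
from .kinetics import PhaseGrid, RateProfiles
from .labeling import LabeledCounts

SPECIES = ("pl", "ml", "pu", "mu")


def write_counts(counts: LabeledCounts, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in SPECIES:
        spio.mmwrite(str(directory / f"{name}.mtx"), getattr(counts, name))
    pd.Series(counts.barcodes).to_csv(
        directory / "barcodes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(counts.genes).to_csv(
        directory / "features.tsv", sep="\t", index=False, header=False
    )
    counts.cells.to_csv(directory / "cells.tsv", sep="\t", index=False)


def read_counts(directory) -> LabeledCounts:
    """Load the four matrices; aligns cell metadata to barcode order.

    Raises a named error when a species matrix is missing or when
    ``cells.tsv`` does not cover every barcode.
    """
    directory = Path(directory)
    missing = [n for n in SPECIES if not (directory / f"{n}.mtx").exists()]
    if missing:
        raise FileNotFoundError(
            f"missing species matrices in {directory}: {', '.join(missing)}"
        )
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    genes = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(directory / "cells.tsv", sep="\t")
    extra = set(barcodes) - set(cells["cell_barcode"])
    if extra:
        raise ValueError(f"barcodes missing from cells.tsv: {sorted(extra)[:5]}")
    cells = (
        cells.set_index("cell_barcode").loc[barcodes].reset_index()
    )
    mats = {
        name: sparse.csr_matrix(spio.mmread(str(directory / f"{name}.mtx")))
        for name in SPECIES
    }
    return LabeledCounts(genes=genes, barcodes=barcodes, cells=cells, **mats)


def write_rate_profiles(rates: RateProfiles, path, bands: dict | None = None) -> None:
    grid = rates.grid
    df = pd.DataFrame(
        {
            "phase_radians": grid.phases,
            "phase_hours": grid.hours(),
            "alpha": rates.alpha,
            "beta": rates.beta,
            "gamma": rates.gamma,
        }
    )
    if bands:
        for key, arr in bands.items():
            if np.ndim(arr) == 2:
                df[f"{key}_lo"], df[f"{key}_hi"] = arr[0], arr[1]
    df.to_csv(path, sep="\t", index=False)


def read_rate_profiles(path, period_hours: float = 19.33) -> RateProfiles:
    df = pd.read_csv(path, sep="\t")
    grid = PhaseGrid(n_points=len(df), period_hours=period_hours)
    return RateProfiles(
        grid,
        alpha=df["alpha"].to_numpy(),
        beta=df["beta"].to_numpy(),
        gamma=df["gamma"].to_numpy(),
    )


@dataclass
class RunConfig:
    """End-to-end pipeline configuration with provenance tracking."""

    output_dir: str = "rnacycle_out"
    counts_dir: str | None = None
    reads_table: str | None = None
    seed: int = 0
    # priors
    eps_s: float = 0.001
    eps_c: float = 1.8e-4
    rho_l: float = 0.024
    # kinetics
    period_hours: float = 19.33
    labeling_time_hours: float = 1.0
    grid_points: int = 500
    rel_tol: float = 1e-6
    max_cycles: int = 100
    model: str = "simplified"
    constant_rate_statistic: str = "mean"
    # analysis
    mode_threshold: float = 0.2
    bootstrap_B: int = 0
    downsample_fractions: tuple = ()
    log_level: str = "INFO"
    # synthetic scenario (simulate subcommand)
    n_cells: int = 1000
    depth: float = 1.0
    capture_sigma: float = 0.3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def grid(self) -> PhaseGrid:
        return PhaseGrid(n_points=self.grid_points, period_hours=self.period_hours)

    def write_provenance(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        record = {
            "package_version": __version__,
            "seed": self.seed,
            "config": dataclasses.asdict(self),
        }
        (directory / "provenance.json").write_text(json.dumps(record, indent=2, default=str))
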