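"""Pipeline composition, configuration, manifests, and table plumbing.

Ties the stages together: simulate (optional) -> quantify -> differential
tests for both comparisons (knockdown vs control, rescue vs knockdown) ->
meta-p ranking and rescue classification -> JSON summary. Every table
written carries the run-manifest hash in a comment header so outputs can
be traced to the configuration that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import classify_rescue, ir_difftest
from .synthetic import SimConfig, simulate_ir_counts
from .thermo import Isotherm, TitrationSeries

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "read_counts_tsv",
    "write_table",
    "write_isotherm_csv",
    "read_isotherm_csv",
    "write_titration_csv",
    "read_titration_csv",
]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run parameters; unknown keys are rejected on load."""

    sim: SimConfig = field(default_factory=SimConfig)
    counts_path: str | None = None  # skip simulation, load this TSV instead
    alpha: float = 0.05
    top_n: int = 1000
    min_overhang: int = 6
    pseudocount: float = 0.5
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = raw.pop("sim", {})
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
        return cls(sim=SimConfig(**sim_raw), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass(frozen=True)
class RunManifest:
    version: str
    config_hash: str
    seed: int
    input_checksums: dict
    timestamp: str

    @property
    def hash(self) -> str:
        return self.config_hash[:12]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _make_manifest(config: PipelineConfig, inputs: dict[str, str]) -> RunManifest:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    checksums = {}
    for name, path in inputs.items():
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        checksums[name] = h
    return RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(payload).hexdigest(),
        seed=config.sim.seed,
        input_checksums=checksums,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    )


def write_table(df: pd.DataFrame, path, manifest: RunManifest | None = None) -> None:
    """Write a TSV with an optional manifest-hash comment header."""
    with open(path, "w") as fh:
        if manifest is not None:
            fh.write(f"# manifest: {manifest.hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the knockdown-rescue analysis end to end; returns the summary.

    Writes counts, truth (when simulated), both comparison tables, rescue
    calls, summary.json, and manifest.json under ``config.out_dir``. On a
    stage failure, partial outputs are removed before re-raising.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    inputs = {}
    if config.counts_path is not None:
        inputs["counts"] = config.counts_path
    manifest = _make_manifest(config, inputs)

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        write_table(df, path, manifest)
        written.append(path)

    try:
        if config.counts_path is None:
            logger.info("simulating %d events (seed %d)", config.sim.n_events, config.sim.seed)
            counts, truth = simulate_ir_counts(config.sim)
            emit("counts.tsv", counts)
            emit("truth.tsv", truth)
        else:
            counts = read_counts_tsv(config.counts_path)

        logger.info("differential test: kd vs ctrl")
        res_kd = ir_difftest(counts, "ctrl", "kd")
        emit("kd_vs_ctrl.tsv", res_kd)
        logger.info("differential test: rescue vs kd")
        res_rescue = ir_difftest(counts, "kd", "rescue")
        emit("rescue_vs_kd.tsv", res_rescue)

        top_n = min(config.top_n, len(res_kd))
        calls, summary = classify_rescue(
            res_kd, res_rescue, top_n=top_n, alpha=config.alpha
        )
        emit("rescue_calls.tsv", calls)

        summary_dict = {
            "n_events": summary.n_events,
            "top_n": summary.top_n,
            "n_significant": summary.n_significant,
            "frac_rescued": summary.frac_rescued,
            "frac_down": summary.frac_down,
            "frac_up": summary.frac_up,
            "manifest": manifest.hash,
        }
        (out / "summary.json").write_text(json.dumps(summary_dict, indent=2))
        written.append(out / "summary.json")
        (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
        return summary_dict
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


# --- biophysics table formats -------------------------------------------------

def write_isotherm_csv(iso: Isotherm, path) -> None:
    """Isotherm CSV: header block (V0, M0, X0, T, per_mole) then injections."""
    with open(path, "w") as fh:
        fh.write(f"# V0_l: {iso.v0}\n")
        fh.write(f"# M0_molar: {iso.cell_conc}\n")
        fh.write(f"# X0_molar: {iso.syringe_conc}\n")
        fh.write(f"# T_kelvin: {iso.temperature}\n")
        fh.write(f"# per_mole: {int(iso.per_mole)}\n")
        fh.write("injection_index,dV_ul,heat\n")
        for i, (dv, q) in enumerate(zip(iso.injection_volumes, iso.heats), start=1):
            fh.write(f"{i},{dv * 1e6:.6g},{q:.10g}\n")


def read_isotherm_csv(path) -> Isotherm:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = float(value)
            body_start = i + 1
        else:
            break
    import io as _io

    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])))
    return Isotherm(
        v0=meta["V0_l"],
        injection_volumes=tuple(df["dV_ul"].to_numpy() * 1e-6),
        cell_conc=meta["M0_molar"],
        syringe_conc=meta["X0_molar"],
        heats=tuple(df["heat"].to_numpy()),
        per_mole=bool(meta.get("per_mole", 1)),
        temperature=meta.get("T_kelvin", 313.0),
    )


def write_titration_csv(series: TitrationSeries, path) -> None:
    """Titration CSV: P0 header, then residue, point, ratio, csp rows."""
    with open(path, "w") as fh:
        fh.write(f"# P0_molar: {series.p0}\n")
        fh.write("residue,point,ratio,csp\n")
        for r, residue in enumerate(series.residues):
            for j, lig in enumerate(series.ligand_concs):
                fh.write(
                    f"{residue},{j},{lig / series.p0:.8g},{series.csp[r, j]:.8g}\n"
                )


def read_titration_csv(path) -> TitrationSeries:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("titration CSV must start with a '# P0_molar:' header")
        p0 = float(first.partition(":")[2])
        df = pd.read_csv(fh)
    residues = list(dict.fromkeys(df["residue"]))
    points = sorted(df["point"].unique())
    csp = np.zeros((len(residues), len(points)))
    ratios = np.zeros(len(points))
    for _, row in df.iterrows():
        r = residues.index(row["residue"])
        j = int(row["point"])
        csp[r, j] = row["csp"]
        ratios[j] = row["ratio"]
    return TitrationSeries(
        p0=p0,
        ligand_concs=tuple(ratios * p0),
        csp=csp,
        residues=tuple(residues),
    )
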