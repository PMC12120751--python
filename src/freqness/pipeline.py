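"""End-to-end orchestration: simulate | scan | randomize | cfc | stats.

``run_pipeline`` executes the stages listed in the config in order, writes
every artifact under the output directory, and records a manifest (config
hash, seeds, package versions, per-stage wall time) sufficient to reproduce
the run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__, cfc, ged, io, randomization, simulate, stats
from .config import load_config, merge_config
from .errors import ConfigurationError, DependencyError
from .filtering import build_frequency_grid

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "scan", "randomize", "cfc", "stats")


def _grid_from_config(config: dict, nyquist: float):
    g = config["grid"]
    return build_frequency_grid(
        stimulation_frequency=g["stimulation_frequency"],
        f_max=g["f_max"],
        step_above=g["step_above"],
        n_below=g["n_below"],
        step_below=g["step_below"],
        sub_stim_centers=g["sub_stim_centers"],
        fwhm_base=g["fwhm_base"],
        fwhm_log10_slope=g["fwhm_log10_slope"],
        nyquist=nyquist,
    )


def _stage_simulate(config: dict, out: Path, state: dict) -> None:
    sim = config["simulate"]
    base = simulate.default_two_network_spec(
        seed=sim["seed"], n_voxels=sim["n_voxels"], duration_s=sim["duration_s"]
    )
    base.sampling_rate = sim["sampling_rate"]
    base.aperiodic_exponent = sim["aperiodic_exponent"]
    base.background_rms = sim["background_rms"]
    base.white_noise_rms = sim["white_noise_rms"]
    coords = simulate.make_lattice_coordinates(sim["n_voxels"])
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    effect = simulate.ConditionEffect(
        added_network=simulate.PlantedNetwork(
            loading=simulate.gaussian_blob_loading(coords, (lo + hi) / 2.0, sigma_mm=12.0),
            center_frequency=sim["pl_add_network_frequency"],
            bandwidth=0.3,
            amplitude=sim["pl_add_network_amplitude"],
        )
    )
    subjects = simulate.simulate_group(
        base, n_subjects=sim["n_subjects"], condition_effect=effect, seed=sim["seed"]
    )
    data_dir = out / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    for record in subjects:
        for condition in ("RS", "PL"):
            io.write_voxel_dataset(
                record[condition], data_dir / f"{record['subject_id']}_{condition}.h5"
            )
    state["subjects"] = subjects


def _require(state: dict, key: str, needed_stage: str) -> None:
    if key not in state:
        raise DependencyError(f"this stage needs outputs of the {needed_stage!r} stage; run it first")


def _stage_scan(config: dict, out: Path, state: dict) -> None:
    _require(state, "subjects", "simulate")
    landscape = None
    for record in state["subjects"]:
        for condition in ("RS", "PL"):
            ds = record[condition]
            grid = _grid_from_config(config, ds.nyquist)
            part = ged.scan_frequencies(
                ds, grid,
                method=config["ged"]["method"],
                n_keep=config["ged"]["n_keep"],
                gamma_S=config["ged"]["gamma_S"],
                gamma_R_fraction=config["ged"]["gamma_R_fraction"],
            )
            if landscape is None:
                landscape = part
            else:
                landscape.merge(part)
    state["landscape"] = landscape
    state["grid"] = _grid_from_config(config, state["subjects"][0]["RS"].nyquist)
    io.write_landscape(landscape, out / "landscape.h5")
    io.landscape_to_tsv(landscape, out / "landscape.tsv")


def _stage_randomize(config: dict, out: Path, state: dict) -> None:
    _require(state, "subjects", "simulate")
    seed = config["pipeline"]["seed"]
    rng = np.random.default_rng(seed)
    shuffled_dir = out / "randomized"
    shuffled_dir.mkdir(parents=True, exist_ok=True)
    for record in state["subjects"]:
        ds = record["RS"]
        shuffled, _ = randomization.label_shuffle(ds, _as_narrow(ds), seed=rng)
        io.write_voxel_dataset(shuffled, shuffled_dir / f"{record['subject_id']}_RS_label.h5")


def _as_narrow(ds):
    # trivial narrowband stand-in so the pair-based shuffle API applies to one matrix
    from .datamodel import NarrowbandDataset

    return NarrowbandDataset(
        data=ds.data, sampling_rate=ds.sampling_rate, subject_id=ds.subject_id,
        condition=ds.condition, center_frequency=1.0, fwhm=1.0,
    )


def _stage_cfc(config: dict, out: Path, state: dict) -> None:
    _require(state, "landscape", "scan")
    rows = []
    for record in state["subjects"]:
        for condition in ("RS", "PL"):
            ds = record[condition]
            profiles = cfc.cfc_scan(
                ds, state["landscape"], state["grid"],
                modulator_frequency=config["cfc"]["modulator_frequency"],
                modulator_component=config["cfc"]["modulator_component"],
                carrier_component=config["cfc"]["carrier_component"],
                n_bins=config["cfc"]["n_bins"],
                edge_guard_s=config["cfc"]["edge_guard_s"],
            )
            for prof in profiles:
                rows.append(
                    (record["subject_id"], condition, prof.modulator_frequency,
                     prof.modulator_component, prof.carrier_frequency,
                     prof.modulation_strength, prof.sine_fit.phase_deg, prof.sine_fit.offset)
                )
    table = pd.DataFrame(
        rows,
        columns=["subject", "condition", "modulator_freq_hz", "modulator_comp",
                 "carrier_freq_hz", "strength", "fit_phase_deg", "fit_offset"],
    )
    table.to_csv(out / "cfc.tsv", sep="\t", index=False)
    state["cfc"] = table


def _split_conditions(landscape):
    from .datamodel import Landscape

    parts = {}
    for condition, grp in landscape.eigenvalues.groupby("condition"):
        sub = Landscape()
        sub._rows = [tuple(r) for r in grp.itertuples(index=False)]
        parts[condition] = sub
    return parts


def _stage_stats(config: dict, out: Path, state: dict) -> None:
    _require(state, "landscape", "scan")
    st = config["stats"]
    parts = _split_conditions(state["landscape"])
    n_keep = config["ged"]["n_keep"]
    table = stats.landscape_contrast(
        parts["PL"], parts["RS"], components=range(1, n_keep + 1), tail=st["tail"], q=st["q"]
    )
    table.to_csv(out / "stats_eigen.tsv", sep="\t", index=False)
    state["stats_eigen"] = table
    if "cfc" in state:
        cfc_table = state["cfc"]
        a = cfc_table[cfc_table["condition"] == "PL"]
        b = cfc_table[cfc_table["condition"] == "RS"]
        mod = stats.modulation_contrast(a, b, tail="right", q=st["q"])
        mod.to_csv(out / "stats_cfc.tsv", sep="\t", index=False)
        state["stats_cfc"] = mod


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "scan": _stage_scan,
    "randomize": _stage_randomize,
    "cfc": _stage_cfc,
    "stats": _stage_stats,
}


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Run the configured stages in order; returns the output directory.

    ``config`` is a config-file path or an override mapping (merged onto the
    defaults).  Any stage failure aborts with an error naming the stage.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        config = merge_config(config)
    stages = config["pipeline"]["stages"]
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        raise ConfigurationError(f"unknown pipeline stage(s): {unknown}")
    out = Path(out_dir if out_dir is not None else config["pipeline"]["out"])
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "versions": {
            "freqness": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
        "stages": [],
    }
    state: dict = {}
    for stage in stages:
        logger.info("stage %s", stage)
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:
            exc.add_note(f"(while running pipeline stage {stage!r})")
            raise
        manifest["stages"].append({"name": stage, "wall_time_s": time.perf_counter() - t0})
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, default=str)
    return out
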