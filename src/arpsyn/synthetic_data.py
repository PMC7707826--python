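"""Seeded generators for every input format the pipeline consumes.

Three generators cover the three data families:

* :func:`gen_pyrene` - plate-reader pyrene trace sets, produced by simulating
  the kinetic models of :mod:`arpsyn.reaction_model` under a condition grid,
  mapping filamentous actin to RFU through a two-point calibration and adding
  Gaussian noise scaled to the dynamic range.
* :func:`gen_patches` - endocytic patch track + cell tables with Poisson
  patch initiation, programmed assembly times and post-peak displacement.
* :func:`gen_census` - replicate counts of Dip1-bound vs total pointed ends
  drawn around a target bound fraction.

Every generator is a pure function of (preset, seed) and records its ground
truth, so downstream measurements can be tested as recovery problems.  The
presets encode the study's reference effect sizes as generative truth (e.g.
wild-type initiation rate 0.030 patches/um^2/s, assembly time 5.1 s); they
exist to validate the measurement pipeline, not the biology.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from arpsyn import reaction_model as rm
from arpsyn.filament_census import CensusRow, CensusTable
from arpsyn.patch_metrics import CellRecord, PatchTrack
from arpsyn.trace_analysis import Calibration, Condition, PolymerizationTrace, TraceSet

# ---------------------------------------------------------------------------
# Pyrene trace presets
# ---------------------------------------------------------------------------

#: Dip1-alone pathway constants used as generative truth (one-monomer model).
DIP1_TRUTH = dict(rm.DIP1_DEFAULTS)

#: Constants for reactions that also contain 1 uM monomeric Wsp1-VCA.  Wsp1
#: is not an explicit species; its monomer recruitment is encoded as a lower
#: Dip1 off-rate (km9), a lower monomer off-rate (km10) and a faster
#: activation step (k11), calibrated once so the full measurement pipeline
#: (max rates -> saturation fits) reports a 1.6-fold plateau increase over
#: the Dip1-alone arm, then frozen.
SYNERGY_TRUTH = {"km9": 0.5, "km10": 12.5, "k11": 0.0245}


@dataclass
class PyrenePreset:
    """Condition grid + truth constants for one pyrene trace-set family."""

    name: str
    conditions: list[Condition]
    rate_constants: dict[str, float] = field(default_factory=lambda: dict(DIP1_TRUTH))
    synergy_constants: dict[str, float] | None = None
    noise_sigma_frac: float = 0.015   # fraction of calibration dynamic range
    t_max_s: float = 2000.0
    dt_s: float = 10.0
    f_min: float = 1000.0
    f_max: float = 11000.0
    total_actin_uM: float = 3.0

    def calibration(self) -> Calibration:
        return Calibration(self.f_min, self.f_max, self.total_actin_uM)


def _titration_conditions(arp23_nM: float, dip1_grid: tuple[float, ...],
                          wsp1_arms: tuple[tuple[str, float], ...]) -> list[Condition]:
    conds = [Condition(actin_uM=3.0)]  # actin-alone control
    for wsp1, wsp1_uM in wsp1_arms:
        for dip1 in dip1_grid:
            conds.append(Condition(actin_uM=3.0, arp23_nM=arp23_nM,
                                   dip1_uM=dip1, wsp1=wsp1, wsp1_uM=wsp1_uM))
    return conds


PYRENE_PRESETS: dict[str, PyrenePreset] = {
    # Dip1 titration at 50 nM Arp2/3 (the model-fitting dataset).
    "dip1-titration": PyrenePreset(
        "dip1-titration",
        _titration_conditions(50.0, (0.0, 0.5, 1.0, 2.5, 5.0, 10.0, 15.0),
                              (("none", 0.0),)),
    ),
    # Paired +/- 1 uM Wsp1-VCA titrations at 10 nM Arp2/3 (the synergy assay).
    "synergy": PyrenePreset(
        "synergy",
        _titration_conditions(10.0, (0.0, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 20.0, 30.0),
                              (("none", 0.0), ("VCA", 1.0))),
        synergy_constants=dict(SYNERGY_TRUTH),
        dt_s=5.0,  # the co-activated reactions are fast; sample accordingly
    ),
}


@dataclass
class PyreneTruth:
    """Ground truth saved alongside a generated pyrene trace set."""

    preset: str
    seed: int
    rate_constants: dict[str, float]
    synergy_constants: dict[str, float] | None
    noiseless_filament_uM: dict[str, list[float]]
    true_max_rate_nM_s: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _network_for(cond: Condition, preset: PyrenePreset) -> rm.ReactionNetwork:
    if cond.arp23_nM == 0 and cond.dip1_uM == 0:
        return rm.build_actin_alone(dict(preset.rate_constants))
    constants = dict(preset.rate_constants)
    if cond.wsp1 in ("VCA", "GST-VCA") and preset.synergy_constants:
        constants.update(preset.synergy_constants)
    return rm.build_dip1_model(1, overrides=constants)


def gen_pyrene(preset: PyrenePreset | str, seed: int) -> tuple[TraceSet, PyreneTruth]:
    """Simulate the preset's condition grid and emit a noisy RFU trace set."""
    if isinstance(preset, str):
        preset = PYRENE_PRESETS[preset]
    rng = np.random.default_rng(seed)
    cal = preset.calibration()
    t = np.arange(0.0, preset.t_max_s + preset.dt_s / 2, preset.dt_s)
    sigma = preset.noise_sigma_frac * (preset.f_max - preset.f_min)

    traces, noiseless, true_rates = [], {}, {}
    for i, cond in enumerate(preset.conditions):
        net = _network_for(cond, preset)
        initial = {"G": cond.actin_uM}
        if cond.arp23_nM > 0 or cond.dip1_uM > 0:
            initial["C"] = cond.arp23_nM / 1000.0
            initial["D"] = cond.dip1_uM
        res = rm.simulate(net, initial, t)
        fil = res.filamentous
        ends = res.ends_spontaneous + res.ends_dip1
        elong = rm.K_ON_BARBED * ends * np.maximum(res["G"] - rm.CRITICAL_CONC, 0.0)
        tag = "aa" if cond.arp23_nM == 0 and cond.dip1_uM == 0 else (
            f"{'p' if cond.wsp1_uM > 0 else 'm'}{cond.dip1_uM:g}")
        trace_id = f"{preset.name}-{i:02d}-{tag}"
        signal = cal.to_rfu(fil)
        if sigma > 0:
            signal = signal + rng.normal(0.0, sigma, size=signal.shape)
        traces.append(PolymerizationTrace(t.copy(), signal, cond, cal, trace_id))
        noiseless[trace_id] = [float(v) for v in fil]
        true_rates[trace_id] = float(elong.max() * 1000.0)

    truth = PyreneTruth(
        preset.name, seed,
        rate_constants=dict(preset.rate_constants),
        synergy_constants=(dict(preset.synergy_constants)
                           if preset.synergy_constants else None),
        noiseless_filament_uM=noiseless,
        true_max_rate_nM_s=true_rates,
    )
    return TraceSet(traces, cal), truth


# ---------------------------------------------------------------------------
# TIRF census simulation preset
# ---------------------------------------------------------------------------

#: Single-filament TIRF census conditions: 1.5 uM actin, 100 nM Arp2/3,
#: 6 nM labeled Dip1 (uM).
TIRF_CENSUS_INITIAL = {"G": 1.5, "C": 0.1, "D": 0.006}

#: Oligomer stabilization factor for TIRF chamber conditions.  Surfaces and
#: methylcellulose crowding make spontaneous nucleation far more productive
#: in TIRF chambers than in plate-reader wells; the factor divides the
#: oligomer off-rates and is calibrated once so the simulated Dip1-origin
#: share of ends at the 150 s census is the encoded 3.4% target.
TIRF_OLIGOMER_STABILIZATION = 9.3935


def census_sim_network() -> rm.ReactionNetwork:
    """One-monomer Dip1 network under TIRF-chamber spontaneous nucleation."""
    z = TIRF_OLIGOMER_STABILIZATION
    overrides = {k: v / z for k, v in rm.SPONTANEOUS_DEFAULTS.items()
                 if k.startswith("kd")}
    return rm.build_dip1_model(1, overrides=overrides)


# ---------------------------------------------------------------------------
# Patch presets
# ---------------------------------------------------------------------------

@dataclass
class PatchPreset:
    """Generative parameters for one strain's endocytic patch phenotype."""

    strain: str
    initiation_rate: float          # patches/um^2/s
    assembly_mean_s: float
    assembly_sd_s: float
    peak_mean: float                # a.u. above background
    peak_sd: float
    internalization_p: float
    decay_mean_s: float = 8.0
    decay_sd_s: float = 2.0
    cell_area_mean_um2: float = 32.0
    cell_area_sd_um2: float = 4.0
    duration_s: float = 60.0        # 1 frame per second
    bg_mean: float = 40.0
    bg_sd: float = 2.0
    intensity_noise_frac: float = 0.10  # of the patch's peak
    whole_cell_level: float = 100.0
    pixel_size_um: float = 0.1

    def __post_init__(self) -> None:
        if self.initiation_rate < 0:
            raise ValueError("initiation rate must be >= 0")
        if not 0.0 <= self.internalization_p <= 1.0:
            raise ValueError("internalization probability must be in [0, 1]")


# Reference strains; initiation rates and assembly times are the study's
# printed wild-type / mutant values, used here as generative truth.
PATCH_PRESETS: dict[str, PatchPreset] = {
    "wt": PatchPreset("wt", 0.030, 5.1, 1.2, 100.0, 15.0, 0.90),
    "dip1d": PatchPreset("dip1d", 0.0076, 4.6, 1.2, 130.0, 20.0, 0.85,
                         whole_cell_level=100.0),
    # 40% initiation-rate decrement relative to wild type; slower assembly.
    "wsp1dCA": PatchPreset("wsp1dCA", 0.018, 6.7, 1.5, 80.0, 15.0, 0.40),
    "wsp1dCA-dip1d": PatchPreset("wsp1dCA-dip1d", 0.0076, 6.9, 1.5, 80.0, 15.0, 0.35),
}


@dataclass
class PatchTruth:
    """Ground truth saved alongside a generated patch dataset."""

    preset: str
    seed: int
    n_cells: int
    initiation_rate: float
    assembly_mean_s: float
    internalization_p: float
    per_patch_assembly_s: dict[str, float]
    per_patch_internalized: dict[str, bool]
    per_cell_new_patches: dict[str, int]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _patch_profile(peak: float, tau: int, decay: int) -> np.ndarray:
    """Background-free intensity profile: linear rise over tau frames from
    appearance to peak, then linear decay over ``decay`` frames."""
    rise = peak * np.arange(1, tau + 2) / (tau + 1)
    fall = peak * (1.0 - np.arange(1, decay + 1) / (decay + 1))
    return np.concatenate([rise, fall])


def gen_patches(
    preset: PatchPreset | str,
    n_cells: int,
    seed: int,
) -> tuple[list[CellRecord], PatchTruth]:
    """Generate per-cell patch track tables for one strain.

    Patch appearances are Poisson in time at the preset's initiation rate;
    patches already underway at movie start are included at steady-state
    abundance so frame-1 exclusion and fate-following have realistic inputs.
    """
    if isinstance(preset, str):
        preset = PATCH_PRESETS[preset]
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    n_frames = int(preset.duration_s)

    cells: list[CellRecord] = []
    assembly_truth: dict[str, float] = {}
    internalized_truth: dict[str, bool] = {}
    new_counts: dict[str, int] = {}

    for ci in range(n_cells):
        cell_id = f"{preset.strain}-c{ci:03d}"
        area = float(np.clip(rng.normal(preset.cell_area_mean_um2,
                                        preset.cell_area_sd_um2), 18.0, 50.0))
        mean_life = preset.assembly_mean_s + preset.decay_mean_s
        n_initial = rng.poisson(preset.initiation_rate * area * mean_life)
        n_new = rng.poisson(preset.initiation_rate * area * preset.duration_s)
        new_counts[cell_id] = int(n_new)

        appearance_times = np.concatenate([
            rng.uniform(-mean_life, 0.0, size=n_initial),
            rng.uniform(0.0, preset.duration_s, size=n_new),
        ])
        background = rng.normal(preset.bg_mean, preset.bg_sd, size=n_frames)

        tracks: list[PatchTrack] = []
        for pi, t0 in enumerate(appearance_times):
            tau = max(1, int(round(rng.normal(preset.assembly_mean_s,
                                              preset.assembly_sd_s))))
            decay = max(2, int(round(rng.normal(preset.decay_mean_s,
                                                preset.decay_sd_s))))
            peak = max(10.0, rng.normal(preset.peak_mean, preset.peak_sd))
            internalized = bool(rng.random() < preset.internalization_p)
            profile = _patch_profile(peak, tau, decay)

            f_app = int(np.floor(t0)) + 1           # 1-based appearance frame
            frames = np.arange(f_app, f_app + len(profile))
            keep = (frames >= 1) & (frames <= n_frames)
            if not keep.any():
                continue
            frames = frames[keep]
            signal = profile[keep]
            peak_pos = int(np.argmax(signal))

            x0, y0 = rng.uniform(5.0, 45.0, size=2)
            x = x0 + rng.normal(0.0, 0.15, size=len(frames))
            y = y0 + rng.normal(0.0, 0.15, size=len(frames))
            if internalized:
                d_final = 2.5 + rng.exponential(1.5)
                theta = rng.uniform(0.0, 2 * np.pi)
                n_post = len(frames) - 1 - peak_pos
                if n_post > 0:
                    ramp = d_final * np.arange(1, n_post + 1) / n_post
                    x[peak_pos + 1:] += np.cos(theta) * ramp
                    y[peak_pos + 1:] += np.sin(theta) * ramp

            noise = rng.normal(0.0, preset.intensity_noise_frac * peak,
                               size=len(frames))
            intensity = np.maximum(background[frames - 1] + signal + noise, 0.0)

            patch_id = f"{cell_id}-p{pi:03d}"
            tracks.append(PatchTrack(patch_id, frames, x, y, intensity,
                                     background[frames - 1]))
            assembly_truth[patch_id] = float(tau)
            internalized_truth[patch_id] = internalized

        cells.append(CellRecord(
            cell_id, tracks, area, preset.pixel_size_um, preset.duration_s,
            preset.strain,
            whole_cell_intensity=float(rng.normal(preset.whole_cell_level,
                                                  preset.whole_cell_level * 0.05)),
            extracellular_background=float(rng.normal(10.0, 1.0)),
        ))

    truth = PatchTruth(
        preset.strain, seed, n_cells, preset.initiation_rate,
        preset.assembly_mean_s, preset.internalization_p,
        assembly_truth, internalized_truth, new_counts,
    )
    return cells, truth


# ---------------------------------------------------------------------------
# Census presets
# ---------------------------------------------------------------------------

@dataclass
class CensusPreset:
    """Target bound fraction and counting depth for census generation."""

    name: str
    bound_fraction: float
    total_mean: float
    correction: float = 1.0
    n_replicates: int = 8

    def __post_init__(self) -> None:
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound fraction must be in [0, 1]")


CENSUS_PRESETS: dict[str, CensusPreset] = {
    # Dip1 + Arp2/3 alone, censused 2.5 min into the reaction: 3.4% of
    # linear pointed ends carry labeled Dip1 (no VCA, correction 1).
    "dip1-alone-2.5min": CensusPreset("dip1-alone-2.5min", 0.034, 2000.0, 1.0),
    # With Wsp1-VCA: a larger decorated fraction, and spontaneous counts are
    # doubled before forming the percentage (VCA halves spontaneous nucleation).
    "plus-wsp1-vca": CensusPreset("plus-wsp1-vca", 0.13, 2000.0, 2.0),
}


def gen_census(
    preset: CensusPreset | str,
    seed: int,
    n_replicates: int | None = None,
) -> tuple[CensusTable, dict]:
    """Draw replicate bound/total pointed-end counts around the preset target."""
    if isinstance(preset, str):
        preset = CENSUS_PRESETS[preset]
    n = n_replicates if n_replicates is not None else preset.n_replicates
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        total = max(1, int(rng.poisson(preset.total_mean)))
        bound = int(rng.binomial(total, preset.bound_fraction))
        rows.append(CensusRow(f"r{i + 1}", preset.name, bound, total,
                              preset.correction))
    truth = {
        "preset": preset.name, "seed": seed,
        "bound_fraction": preset.bound_fraction,
        "total_mean": preset.total_mean,
        "correction": preset.correction,
    }
    return CensusTable(rows, {preset.name: truth}), truth
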