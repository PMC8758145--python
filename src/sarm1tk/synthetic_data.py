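"""Seeded generators emulating the study's experimental data structures.

Three generators mirror the three experimental readouts:

* dose-response tables of NADase fold-activation vs effector concentration
  (triplicate points on a log grid, multiplicative lognormal noise — fold
  responses are positive ratios);
* discontinuous-assay time courses at 250 µM NAD with linear early-phase
  accumulation of ADPR and cADPR (additive Gaussian noise on concentrations,
  total product capped at the substrate supply);
* one-site ITC isotherms under the standard titration geometry (additive
  Gaussian noise on integrated heats).

Scenario presets encode the qualitative behaviours of the study system:
VMN is a potent biphasic activator of hSARM1 (activation at low µM, loss of
activity at high concentration), NMN a weaker monotone activator on the
tested range, and the K193R pocket mutant responds to neither; "neutral"
is a flat no-effect control.  Every generator is a pure function of its
inputs and seed; per-stream seeds are spawned from the global seed with
numpy's SeedSequence so streams are independent but reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assay_rates import TimeCourse
from .itc_binding import BindingParams, ITCProtocol, Isotherm, simulate_isotherm
from .kinetic_model import DoseResponseTable, DualEffectorParams, fold_activation, rate

__all__ = [
    "ScenarioPreset",
    "PRESETS",
    "get_preset",
    "gen_dose_response",
    "gen_time_course",
    "gen_isotherm",
]

#: default dose grid, µM: zero anchor plus a log ladder spanning both the
#: activation (low µM) and inhibition (high µM-mM) limbs
DEFAULT_GRID = (0.0, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0)


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    params: DualEffectorParams
    grid: tuple[float, ...] = DEFAULT_GRID
    noise_cv: float = 0.05
    description: str = ""


# Basal activities follow the printed values (hSARM1 18.12, K193R 17.75
# milliU/mg); Km(NAD) = 70 µM throughout.  Effector parameters encode the
# qualitative curve shapes: VMN biphasic with low-µM Ka (cf. its 2.83 µM
# ARM-domain Kd) and an inhibitory limb two orders above; NMN monotone on
# the tested range with a higher Ka and weaker induction; K193R flat.
PRESETS: dict[str, ScenarioPreset] = {
    "hSARM1_VMN": ScenarioPreset(
        name="hSARM1_VMN",
        params=DualEffectorParams(
            vmax=18.12, km=70.0, x_act=10.0, y_res=0.15,
            ka=3.0, ki=300.0, n_act=2.0, n_inh=2.0,
        ),
        description="biphasic VMN activation of wild-type hSARM1",
    ),
    "hSARM1_NMN": ScenarioPreset(
        name="hSARM1_NMN",
        params=DualEffectorParams(
            vmax=18.12, km=70.0, x_act=5.0, y_res=1.0,
            ka=30.0, ki=1e6, n_act=2.0, n_inh=2.0,
        ),
        description="monotone NMN activation of wild-type hSARM1",
    ),
    "K193R_any": ScenarioPreset(
        name="K193R_any",
        params=DualEffectorParams(
            vmax=17.75, km=70.0, x_act=1.0, y_res=1.0,
            ka=10.0, ki=1e6, n_act=1.0, n_inh=1.0,
        ),
        description="pocket mutant: no response to VMN or NMN",
    ),
    "neutral": ScenarioPreset(
        name="neutral",
        params=DualEffectorParams(
            vmax=18.12, km=70.0, x_act=1.0, y_res=1.0,
            ka=10.0, ki=1e6, n_act=1.0, n_inh=1.0,
        ),
        description="flat control: effector without effect",
    ),
}


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def _stream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def gen_dose_response(
    preset: ScenarioPreset | str,
    replicates: int = 3,
    noise_cv: float | None = None,
    seed: int = 0,
) -> DoseResponseTable:
    """Fold-activation table on the preset's dose grid.

    Noise is multiplicative lognormal with the requested coefficient of
    variation (``noise_cv=0`` reproduces the model exactly).
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    cv = preset.noise_cv if noise_cv is None else float(noise_cv)
    if cv < 0:
        raise ValueError("noise_cv must be non-negative")
    grid = np.asarray(preset.grid, dtype=float)
    conc = np.tile(grid, replicates)
    rep = np.repeat(np.arange(replicates), len(grid))
    clean = fold_activation(conc, preset.params)
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        mu = -0.5 * sigma**2  # unit-mean lognormal
        rng = _stream(seed, 0)
        noise = np.exp(rng.normal(mu, sigma, size=conc.shape))
        responses = clean * noise
    else:
        responses = clean
    return DoseResponseTable(
        effector=preset.name,
        concentrations=conc,
        responses=responses,
        response_kind="fold",
        replicates=rep,
    )


def gen_time_course(
    params: DualEffectorParams,
    s0: float = 250.0,
    i_conc: float = 0.0,
    enzyme: float = 10.0,
    times=(0.0, 2.0, 4.0, 6.0, 8.0, 10.0),
    cadpr_fraction: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TimeCourse:
    """Linear early-phase product accumulation for the discontinuous assay.

    The generating rate is rate(s0, i_conc, params) in milliU/mg converted to
    µM/min through the enzyme concentration; products split between ADPR and
    cADPR by ``cadpr_fraction`` and the total is capped at ``s0`` (substrate
    exhaustion).  Additive Gaussian noise in µM, clipped at zero.
    """
    if not 0 <= cadpr_fraction <= 1:
        raise ValueError("cadpr_fraction must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    times = np.asarray(times, dtype=float)
    v_specific = rate(s0, i_conc, params)  # milliU/mg = nmol/min/mg
    slope = v_specific * (enzyme / 1000.0)  # µM/min at enzyme µg/ml
    total = np.minimum(slope * times, s0)
    adpr = total * (1.0 - cadpr_fraction)
    cadpr = total * cadpr_fraction
    if noise_sd > 0:
        rng = _stream(seed, 1)
        adpr = np.clip(adpr + rng.normal(0, noise_sd, adpr.shape), 0, None)
        cadpr = np.clip(cadpr + rng.normal(0, noise_sd, cadpr.shape), 0, None)
    return TimeCourse(
        times=times,
        products={"ADPR": adpr, "cADPR": cadpr},
        s0=s0,
        enzyme_conc=enzyme,
    )


def gen_isotherm(
    protocol: ITCProtocol,
    params: BindingParams,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Isotherm:
    """One-site isotherm with additive Gaussian heat noise (µJ)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    iso = simulate_isotherm(protocol, params)
    if noise_sd > 0:
        rng = _stream(seed, 2)
        iso = Isotherm(
            heats=iso.heats + rng.normal(0, noise_sd, iso.heats.shape),
            molar_ratios=iso.molar_ratios,
        )
    return iso
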