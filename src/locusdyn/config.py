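"""Configuration objects for simulation, population synthesis and pipeline runs.

Defaults mirror the imaging conditions of the study system: 109.76 nm pixels
on a 512x512 camera and a 4.23 s frame interval, with the attB locus moving
as anisotropic fractional Brownian motion (longitudinal exponent 0.426,
transversal 0.247) and behaviour classes mixed at the observed population
fractions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

#: camera resolution, nm per pixel
PIXEL_SIZE_NM: float = 109.76
#: default interval between successive frames, seconds
FRAME_INTERVAL_S: float = 4.23
#: alternative acquisition intervals, seconds
SLOW_FRAME_INTERVALS_S: tuple[float, float] = (30.0, 120.0)

#: behaviour classes an element trajectory can be assigned to
BEHAVIOR_LABELS: tuple[str, ...] = ("integrated", "mobile_fast", "mobile_local", "trapped")

#: default behaviour-class mixture: 45% mobile without integration
#: (14% fast cell-spanning + 31% locally mobile), small trapped minority,
#: remainder integrated
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "integrated": 0.50,
    "mobile_fast": 0.14,
    "mobile_local": 0.31,
    "trapped": 0.05,
}

#: attB generating parameters per axis (x = transversal, y = longitudinal).
#: Exponents are the study's reported per-axis values; the apparent diffusion
#: coefficients are chosen so the per-frame displacement is ~50 nm per axis,
#: typical of chromosomal loci (the source reports D only graphically).
ATTB_ALPHA_Y: float = 0.426
ATTB_ALPHA_X: float = 0.247
ATTB_D_Y: float = 1350.0  # nm^2 / s^alpha_y
ATTB_D_X: float = 1050.0  # nm^2 / s^alpha_x
#: 2D attB MSD exponent (isotropic effective fit)
ATTB_ALPHA_2D: float = 0.36


@dataclass
class SimConfig:
    """Parameters of a stochastic trajectory simulation.

    ``model`` selects fractional Brownian motion (``fbm``), a heavy-tailed
    continuous-time random walk (``ctrw``), or obstructed lattice diffusion
    (``od``).  Exponents and diffusion coefficients are per axis
    (x transversal, y longitudinal); ``D`` has units nm^2/s^alpha.
    """

    model: str = "fbm"
    alpha_x: float = ATTB_ALPHA_X
    alpha_y: float = ATTB_ALPHA_Y
    D_x: float = ATTB_D_X
    D_y: float = ATTB_D_Y
    dt: float = FRAME_INTERVAL_S
    n_frames: int = 90
    n_traj: int = 1
    seed: int = 0
    ctrw_beta: float = 0.5
    od_obstacle_density: float = 0.35

    def __post_init__(self) -> None:
        if self.model not in ("fbm", "ctrw", "od"):
            raise ValueError(f"unknown model {self.model!r}; expected fbm, ctrw or od")
        for name in ("alpha_x", "alpha_y"):
            a = getattr(self, name)
            if not 0.0 < a <= 1.0:
                raise ValueError(f"{name}={a} outside (0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if not 0.0 < self.ctrw_beta < 1.0:
            raise ValueError("ctrw_beta must lie in (0, 1)")
        if not 0.0 <= self.od_obstacle_density < 1.0:
            raise ValueError("od_obstacle_density must lie in [0, 1)")


@dataclass
class PopulationConfig:
    """Parameters of a synthetic transconjugant population.

    Each cell is a stadium (spherocylinder cross-section) of the given
    length/width, carries two attB loci anchored at the configured fractions
    of the long axis and one element trajectory drawn from the behaviour
    mixture.  Camera parameters feed the renderer (photon counts per spot,
    Poisson shot noise, Gaussian read noise, constant background).
    """

    n_cells: int = 100
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    cell_length_mean: float = 3000.0  # nm
    cell_length_sd: float = 300.0  # nm
    cell_width: float = 900.0  # nm
    attB_longitudinal_positions: tuple[float, ...] = (0.25, 0.75)
    attB_alpha_x: float = ATTB_ALPHA_X
    attB_alpha_y: float = ATTB_ALPHA_Y
    attB_D_x: float = ATTB_D_X  # nm^2/s^alpha_x
    attB_D_y: float = ATTB_D_Y  # nm^2/s^alpha_y
    tether_distance: float = 200.0  # nm, integrated-pair offset
    pixel_size: float = PIXEL_SIZE_NM
    psf_sigma: float = 130.0  # nm
    photon_budget: float = 1500.0  # photons per spot
    read_noise: float = 2.0  # electrons rms
    background: float = 100.0  # photons per pixel
    dt: float = FRAME_INTERVAL_S
    n_frames: int = 90
    image_shape: tuple[int, int] = (512, 512)
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.class_fractions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, expected 1")
        unknown = set(self.class_fractions) - set(BEHAVIOR_LABELS)
        if unknown:
            raise ValueError(f"unknown behaviour labels: {sorted(unknown)}")
        if not all(0.0 < p < 1.0 for p in self.attB_longitudinal_positions):
            raise ValueError("attB longitudinal positions must lie in (0, 1)")
        if self.cell_length_mean <= self.cell_width:
            raise ValueError("cells must be longer than wide")


#: named condition presets: drug-like perturbations are modelled purely as
#: alternative generator parameter sets (exponents, mobility, class mixture)
CONDITION_PRESETS: dict[str, dict] = {
    "untreated": {},
    "rifampicin-like": {
        # nucleoid expansion: ~3x larger apparent D, much larger fast fraction
        "D_scale": 3.0,
        "class_fractions": {
            "integrated": 0.14,
            "mobile_fast": 0.76,
            "mobile_local": 0.08,
            "trapped": 0.02,
        },
    },
    "chloramphenicol-like": {
        # nucleoid compaction: isotropic exponents, halved mobile fraction
        "alpha_x": 0.309,
        "alpha_y": 0.30,
        "class_fractions": {
            "integrated": 0.72,
            "mobile_fast": 0.05,
            "mobile_local": 0.18,
            "trapped": 0.05,
        },
    },
    "dnp-like": {
        # ATP/GTP depletion: strongly reduced exponents, moderately lower D
        "alpha_x": 0.15,
        "alpha_y": 0.25,
        "D_scale": 0.6,
    },
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    stages: tuple[str, ...] = (
        "simulate",
        "render",
        "localize",
        "track",
        "analyze",
        "classify",
    )
    condition: str = "untreated"
    seed: int = 0
    out_dir: str = "runs/latest"
    pixel_size: float = PIXEL_SIZE_NM
    dt: float = FRAME_INTERVAL_S
    population: PopulationConfig = field(default_factory=PopulationConfig)
    threshold_k: float = 5.0
    max_disp: float = 800.0  # nm
    max_gap: int = 2  # frames
    min_len: int = 20  # frames
    fit_lag_range: tuple[int, int] = (2, 10)
    vacf_deltas: tuple[int, ...] = (1, 2, 4, 8)
    localization_noise: float = 20.0  # nm per axis, trajectory-only mode

    def __post_init__(self) -> None:
        if self.condition not in CONDITION_PRESETS:
            raise ValueError(
                f"unknown condition {self.condition!r}; "
                f"known: {sorted(CONDITION_PRESETS)}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["population"]["class_fractions"] = dict(self.population.class_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        pop = d.pop("population", {})
        if isinstance(pop, PopulationConfig):
            population = pop
        else:
            pop = dict(pop)
            for key in ("attB_longitudinal_positions", "image_shape"):
                if key in pop:
                    pop[key] = tuple(pop[key])
            population = PopulationConfig(**pop)
        for key in ("stages", "fit_lag_range", "vacf_deltas"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(population=population, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
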