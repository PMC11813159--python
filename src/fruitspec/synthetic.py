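"""Seeded synthetic fruit datasets: ripening-stage traits plus coupled spectra.

The generator emulates the sampling frame of a mango/strawberry ripening
study: 75 mango samples (25 per stage) with SPAD, TSS and firmness, and 45
strawberry samples (15 per stage) with L*, b*, TSS and firmness.  Stage trait
distributions are truncated normals parameterized by the published per-stage
(min, max, mean, SD) summaries; the sampler is location-calibrated so the
truncated distribution's mean equals the configured mean even for strongly
skewed cells.

Spectra are built on the canonical 302-1148 nm grid by a deliberately simple
parametric forward model (not a radiative-transfer model): a logistic red
edge between a visible baseline and an NIR plateau, a green reflectance peak,
a red (anthocyanin-era) shoulder, Gaussian chlorophyll (672 nm) and water
(970 nm) absorption features, and a gentle NIR tilt.  Each feature amplitude
is a linear function of one normalized trait, so every trait has a designed,
recoverable spectral driver:

* mango    — SPAD -> chlorophyll depth / red edge, TSS -> NIR tilt
             (the RSI 764/766 family), firmness -> 970 nm water feature.
* strawberry — L* -> green peak, b* -> red shoulder (the RSI 666/636 family),
             TSS -> NIR tilt, firmness -> chlorophyll depth / red edge.

Noise: one multiplicative illumination factor per sample (spectral indices
are ratio-based precisely to cancel this) plus independent additive noise per
band.  The stored ground truth can invert noiseless spectra back to the
generating traits exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.special import expit
from scipy.stats import truncnorm

from .spectra import (
    CANONICAL_WAVELENGTHS,
    STAGES,
    SpectraSet,
    TraitTable,
    canonical_grid,
    write_spectra,
    write_traits,
)

__all__ = [
    "TraitStageParams",
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticDataset",
    "MANGO_TRAIT_PARAMS",
    "STRAWBERRY_TRAIT_PARAMS",
    "generate_traits",
    "generate_spectra",
    "generate_dataset",
]


@dataclass(frozen=True)
class TraitStageParams:
    """Truncated-normal parameters of one trait within one stage."""

    min: float
    max: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise ValueError(f"infeasible truncation: min {self.min} > max {self.max}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not (self.min <= self.mean <= self.max):
            raise ValueError("mean must lie within [min, max]")


# Per-stage (min, max, mean, SD) trait parameters of the emulated study.
MANGO_TRAIT_PARAMS: dict[str, dict[str, TraitStageParams]] = {
    "SPAD": {
        "unripe": TraitStageParams(19.50, 36.00, 27.56, 4.53),
        "ripe": TraitStageParams(0.20, 18.50, 6.23, 5.54),
        "overripe": TraitStageParams(0.00, 0.20, 0.06, 0.07),
    },
    "TSS": {
        "unripe": TraitStageParams(8.20, 15.90, 11.98, 2.24),
        "ripe": TraitStageParams(16.60, 19.00, 17.81, 0.74),
        "overripe": TraitStageParams(17.80, 21.90, 19.93, 1.07),
    },
    "firmness": {
        "unripe": TraitStageParams(5.90, 42.50, 24.68, 9.50),
        "ripe": TraitStageParams(1.30, 5.85, 2.24, 1.29),
        "overripe": TraitStageParams(0.00, 1.25, 0.78, 0.39),
    },
}

STRAWBERRY_TRAIT_PARAMS: dict[str, dict[str, TraitStageParams]] = {
    "L": {
        "unripe": TraitStageParams(35.20, 43.32, 39.62, 2.18),
        "ripe": TraitStageParams(31.44, 42.24, 35.43, 2.61),
        "overripe": TraitStageParams(29.84, 33.47, 31.35, 1.04),
    },
    "b": {
        "unripe": TraitStageParams(22.19, 26.92, 24.46, 1.42),
        "ripe": TraitStageParams(19.38, 24.87, 21.80, 1.84),
        "overripe": TraitStageParams(13.21, 17.83, 15.52, 1.44),
    },
    "TSS": {
        "unripe": TraitStageParams(7.50, 9.70, 8.53, 0.47),
        "ripe": TraitStageParams(8.50, 10.00, 9.33, 0.51),
        "overripe": TraitStageParams(9.70, 12.10, 10.42, 0.59),
    },
    "firmness": {
        "unripe": TraitStageParams(5.63, 7.92, 7.09, 0.69),
        "ripe": TraitStageParams(4.47, 6.97, 5.92, 0.69),
        "overripe": TraitStageParams(3.28, 4.53, 3.84, 0.36),
    },
}

# Spectral forward-model parameters.  Each absorption/reflection feature is
# (base amplitude, amplitude range, driving trait, invert flag); amplitude =
# base + range * u or base + range * (1 - u) with u the [0, 1]-normalized
# driver trait.
_MANGO_SPECTRAL = {
    "vis_level": 0.10,
    "plateau": 0.55,
    "edge_width": 14.0,
    "edge_pos_base": 686.0, "edge_pos_range": 24.0, "edge_driver": "SPAD",
    "green": {"center": 554.0, "sigma": 28.0, "base": 0.04, "range": 0.05,
              "driver": "SPAD", "invert": False},
    "red": {"center": 640.0, "sigma": 26.0, "base": 0.0, "range": 0.0,
            "driver": None, "invert": False},
    "chl": {"center": 672.0, "sigma": 24.0, "base": 0.02, "range": 0.09,
            "driver": "SPAD", "invert": False},
    "water": {"center": 970.0, "sigma": 40.0, "base": 0.02, "range": 0.12,
              "driver": "firmness", "invert": True},
    "tilt_slope": 0.5, "tilt_driver": "TSS",
    "tilt_anchor": 860.0, "tilt_scale": 240.0,
    "tilt_onset": 742.0, "tilt_sharpness": 3.0,
}

_STRAWBERRY_SPECTRAL = {
    "vis_level": 0.10,
    "plateau": 0.55,
    "edge_width": 14.0,
    "edge_pos_base": 684.0, "edge_pos_range": 18.0, "edge_driver": "firmness",
    "green": {"center": 554.0, "sigma": 28.0, "base": 0.02, "range": 0.12,
              "driver": "L", "invert": False},
    "red": {"center": 640.0, "sigma": 26.0, "base": 0.01, "range": 0.14,
            "driver": "b", "invert": True},
    "chl": {"center": 672.0, "sigma": 24.0, "base": 0.02, "range": 0.06,
            "driver": "firmness", "invert": False},
    "water": {"center": 970.0, "sigma": 40.0, "base": 0.04, "range": 0.0,
              "driver": None, "invert": False},
    "tilt_slope": 0.4, "tilt_driver": "TSS",
    "tilt_anchor": 860.0, "tilt_scale": 240.0,
    "tilt_onset": 742.0, "tilt_sharpness": 3.0,
}

#: Wavelengths used to invert the noiseless forward model back to traits.
_PROBE_BANDS = {
    "mango": (672.0, 780.0, 970.0),
    "strawberry": (554.0, 640.0, 672.0, 800.0),
}

#: The spectral region each trait is designed to drive (for reporting).
_DESIGNED_DRIVERS = {
    "mango": {
        "SPAD": {"region": "red / red edge", "bands": (672, 700)},
        "TSS": {"region": "NIR tilt", "bands": (764, 766)},
        "firmness": {"region": "970 nm water feature", "bands": (970, 1000)},
    },
    "strawberry": {
        "L": {"region": "green peak", "bands": (554, 677)},
        "b": {"region": "red shoulder", "bands": (666, 636)},
        "TSS": {"region": "NIR tilt", "bands": (760, 858)},
        "firmness": {"region": "chlorophyll dip / red edge", "bands": (670, 610)},
    },
}


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic dataset.

    ``n_per_stage`` is an int (same count per stage) or a 3-tuple in stage
    order; defaults are 25/stage for mango and 15/stage for strawberry.
    Noise: ``noise_multiplicative`` is the SD of a per-sample illumination
    factor (1 + eps); ``noise_additive`` the SD of per-band additive noise.
    """

    fruit_type: str
    n_per_stage: int | tuple[int, int, int]
    seed: int = 0
    trait_params: dict[str, dict[str, TraitStageParams]] = field(default_factory=dict)
    spectral: dict = field(default_factory=dict)
    noise_multiplicative: float = 0.05
    noise_additive: float = 0.005

    def __post_init__(self) -> None:
        if self.fruit_type not in ("mango", "strawberry"):
            raise ValueError(f"unknown fruit_type {self.fruit_type!r}")
        if isinstance(self.n_per_stage, int):
            self.n_per_stage = (self.n_per_stage,) * 3
        if any(n < 1 for n in self.n_per_stage):
            raise ValueError("n_per_stage must be >= 1")
        if self.noise_multiplicative < 0 or self.noise_additive < 0:
            raise ValueError("noise SDs must be >= 0")
        if not self.trait_params:
            self.trait_params = (MANGO_TRAIT_PARAMS if self.fruit_type == "mango"
                                 else STRAWBERRY_TRAIT_PARAMS)
        if not self.spectral:
            self.spectral = (_MANGO_SPECTRAL if self.fruit_type == "mango"
                             else _STRAWBERRY_SPECTRAL)

    @classmethod
    def mango(cls, seed: int = 0, **kwargs) -> "GeneratorConfig":
        kwargs.setdefault("n_per_stage", 25)
        return cls(fruit_type="mango", seed=seed, **kwargs)

    @classmethod
    def strawberry(cls, seed: int = 0, **kwargs) -> "GeneratorConfig":
        kwargs.setdefault("n_per_stage", 15)
        return cls(fruit_type="strawberry", seed=seed, **kwargs)

    def trait_bounds(self, trait: str) -> tuple[float, float]:
        """Overall (min, max) of a trait across all stages."""
        stages = self.trait_params[trait]
        return (min(p.min for p in stages.values()),
                max(p.max for p in stages.values()))


# ---------------------------------------------------------------------------
# Trait sampling
# ---------------------------------------------------------------------------

def _calibrated_truncnorm(p: TraitStageParams):
    """Frozen truncated normal on [min, max] whose *truncated* mean equals
    ``p.mean`` (location solved numerically; scale fixed at ``p.sd``)."""
    if p.sd == 0 or p.min == p.max:
        return None

    def trunc_mean(loc: float) -> float:
        a, b = (p.min - loc) / p.sd, (p.max - loc) / p.sd
        return float(truncnorm.mean(a, b, loc=loc, scale=p.sd))

    lo, hi = p.min - 10 * p.sd, p.max + 10 * p.sd
    # trunc_mean is increasing in loc; bracket and solve
    loc = optimize.brentq(lambda m: trunc_mean(m) - p.mean, lo, hi, xtol=1e-12)
    a, b = (p.min - loc) / p.sd, (p.max - loc) / p.sd
    return truncnorm(a, b, loc=loc, scale=p.sd)


def generate_traits(cfg: GeneratorConfig) -> TraitTable:
    """Draw per-stage trait vectors from calibrated truncated normals."""
    rng = np.random.default_rng([cfg.seed, 0])
    ids: list[str] = []
    stages: list[str] = []
    traits: dict[str, list[float]] = {name: [] for name in cfg.trait_params}
    for stage, n in zip(STAGES, cfg.n_per_stage):
        for i in range(n):
            ids.append(f"{cfg.fruit_type}-{stage}-{i + 1:03d}")
            stages.append(stage)
        for name, per_stage in cfg.trait_params.items():
            p = per_stage[stage]
            dist = _calibrated_truncnorm(p)
            if dist is None:
                draws = np.full(n, p.mean)
            else:
                draws = dist.rvs(size=n, random_state=rng)
            traits[name].extend(draws.tolist())
    return TraitTable(
        sample_ids=ids, stage=stages,
        traits={k: np.asarray(v) for k, v in traits.items()},
        fruit_type=cfg.fruit_type,
    )


# ---------------------------------------------------------------------------
# Spectral forward model
# ---------------------------------------------------------------------------

def _gauss(lam: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2)


def _feature_amplitude(feature: dict, u: dict[str, float]) -> float:
    driver = feature["driver"]
    if driver is None or feature["range"] == 0:
        return feature["base"]
    x = u[driver]
    if feature["invert"]:
        x = 1.0 - x
    return feature["base"] + feature["range"] * x


def _forward_spectrum(u: dict[str, float], lam: np.ndarray, sp: dict) -> np.ndarray:
    """Noiseless reflectance from normalized traits ``u`` (each in [0, 1])."""
    pos = sp["edge_pos_base"] + sp["edge_pos_range"] * u[sp["edge_driver"]]
    r = sp["vis_level"] + (sp["plateau"] - sp["vis_level"]) * expit(
        (lam - pos) / sp["edge_width"])
    for key in ("green", "red"):
        f = sp[key]
        r = r + _feature_amplitude(f, u) * _gauss(lam, f["center"], f["sigma"])
    for key in ("chl", "water"):
        f = sp[key]
        r = r - _feature_amplitude(f, u) * _gauss(lam, f["center"], f["sigma"])
    s = sp["tilt_slope"] * (u[sp["tilt_driver"]] - 0.5)
    window = expit((lam - sp["tilt_onset"]) / sp["tilt_sharpness"])
    r = r * (1.0 + s * (lam - sp["tilt_anchor"]) / sp["tilt_scale"] * window)
    return r


def _normalize_traits(t: TraitTable, cfg: GeneratorConfig) -> list[dict[str, float]]:
    bounds = {name: cfg.trait_bounds(name) for name in cfg.trait_params}
    out = []
    for i in range(t.n_samples):
        u = {}
        for name, (lo, hi) in bounds.items():
            span = hi - lo if hi > lo else 1.0
            u[name] = float((t.values(name)[i] - lo) / span)
        out.append(u)
    return out


def generate_spectra(t: TraitTable, cfg: GeneratorConfig) -> SpectraSet:
    """Trait-coupled reflectance spectra on the canonical grid.

    Deterministic under ``cfg.seed``; two samples with identical traits and
    zero noise receive identical spectra.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    lam = CANONICAL_WAVELENGTHS
    rows = np.empty((t.n_samples, lam.size))
    for i, u in enumerate(_normalize_traits(t, cfg)):
        rows[i] = _forward_spectrum(u, lam, cfg.spectral)
    if cfg.noise_multiplicative > 0:
        rows *= 1.0 + rng.normal(0.0, cfg.noise_multiplicative, size=(t.n_samples, 1))
    if cfg.noise_additive > 0:
        rows += rng.normal(0.0, cfg.noise_additive, size=rows.shape)
    np.clip(rows, 0.0, None, out=rows)
    return SpectraSet(grid=canonical_grid(), reflectance=rows,
                      sample_ids=list(t.sample_ids), fruit_type=cfg.fruit_type)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """The designed trait-spectrum coupling of a synthetic dataset.

    ``drivers`` documents, per trait, the spectral region and canonical band
    pair it is designed to drive plus the noise levels.  ``recover_traits``
    inverts the exact forward model at a handful of probe wavelengths, so at
    zero noise the generating traits are recovered to numerical precision.
    """

    fruit_type: str
    trait_params: dict[str, dict[str, TraitStageParams]]
    spectral: dict
    drivers: dict[str, dict]
    noise_multiplicative: float
    noise_additive: float

    @property
    def trait_names(self) -> list[str]:
        return list(self.trait_params)

    def _bounds(self, trait: str) -> tuple[float, float]:
        stages = self.trait_params[trait]
        return (min(p.min for p in stages.values()),
                max(p.max for p in stages.values()))

    def recover_traits(self, spectra: SpectraSet) -> dict[str, np.ndarray]:
        """Invert noiseless spectra back to traits via the forward model."""
        names = self.trait_names
        probes = np.asarray(_PROBE_BANDS[self.fruit_type])
        cols = [spectra.grid.index_of(nm) for nm in probes]
        observed = spectra.reflectance[:, cols]

        def residual(x: np.ndarray, target: np.ndarray) -> np.ndarray:
            u = dict(zip(names, x))
            return _forward_spectrum(u, probes, self.spectral) - target

        recovered = np.empty((spectra.n_samples, len(names)))
        x0 = np.full(len(names), 0.5)
        for i in range(spectra.n_samples):
            sol = optimize.root(residual, x0, args=(observed[i],), method="hybr",
                                tol=1e-14)
            recovered[i] = sol.x
        out = {}
        for j, name in enumerate(names):
            lo, hi = self._bounds(name)
            out[name] = lo + recovered[:, j] * (hi - lo)
        return out

    def manifest(self) -> dict:
        return {
            "fruit_type": self.fruit_type,
            "noise_multiplicative": self.noise_multiplicative,
            "noise_additive": self.noise_additive,
            "drivers": self.drivers,
            "trait_params": {
                trait: {stage: asdict(p) for stage, p in stages.items()}
                for trait, stages in self.trait_params.items()
            },
        }


@dataclass
class SyntheticDataset:
    """A generated spectra + trait pair with its ground truth."""

    spectra: SpectraSet
    traits: TraitTable
    ground_truth: GroundTruth
    config: GeneratorConfig


def generate_dataset(cfg: GeneratorConfig, out_dir: str | Path | None = None
                     ) -> SyntheticDataset:
    """Compose trait and spectra generation; optionally write fixture files
    (spectra CSV, traits CSV, ground-truth manifest JSON)."""
    traits = generate_traits(cfg)
    spectra = generate_spectra(traits, cfg)
    gt = GroundTruth(
        fruit_type=cfg.fruit_type,
        trait_params=cfg.trait_params,
        spectral=cfg.spectral,
        drivers={
            name: dict(_DESIGNED_DRIVERS[cfg.fruit_type][name],
                       noise_multiplicative=cfg.noise_multiplicative,
                       noise_additive=cfg.noise_additive)
            for name in cfg.trait_params
        },
        noise_multiplicative=cfg.noise_multiplicative,
        noise_additive=cfg.noise_additive,
    )
    ds = SyntheticDataset(spectra=spectra, traits=traits, ground_truth=gt, config=cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = f"seed={cfg.seed}"
        write_spectra(spectra, out / f"{cfg.fruit_type}_spectra.csv",
                      header_comment=f"fruitspec synthetic spectra {tag}")
        write_traits(traits, out / f"{cfg.fruit_type}_traits.csv",
                     header_comment=f"fruitspec synthetic traits {tag}")
        with open(out / f"{cfg.fruit_type}_ground_truth.json", "w") as fh:
            json.dump(gt.manifest(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return ds
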