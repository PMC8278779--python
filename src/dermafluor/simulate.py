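"""Synthetic lesions and cohorts with the statistical structure of real scans.

No spectra from the clinical study are deposited, so this module generates
labeled stand-ins: each lesion is a few hundred spectra drawn from the
phenotype templates with heteroscedastic count noise, a configurable
fraction of uninformative background spectra, and ~5% low-SNR spectra that
the preprocessing stage is expected to reject.  Truth labels ride along in
spectrum metadata and are never consulted by classification.

Noise model: Gaussian with sigma = noise_level * sqrt(counts + 1), a
Poisson-like surrogate for detector count noise, clipped at zero.
Seed-splitting: lesion ``i`` of a cohort uses
``SeedSequence([master_seed, i])`` so cohorts are reproducible across runs
and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fluorophores import Phenotype, compose_template
from .spectra import Diagnosis, LesionScan, Spectrum, Stage, WavelengthGrid, make_default_grid

__all__ = [
    "LesionRecipe",
    "CohortRecipe",
    "generate_spectrum",
    "generate_low_snr_spectrum",
    "generate_lesion",
    "generate_cohort",
    "DEFAULT_TYPE_MIXES",
]

#: Detector counts corresponding to template intensity 1.0.
DEFAULT_COUNTS_SCALE = 2000.0
#: Relative width of the count-noise surrogate (1.0 = Poisson-equivalent).
DEFAULT_NOISE_LEVEL = 1.0
#: Fraction of acquired spectra with too little signal for analysis.
DEFAULT_LOW_SNR_FRACTION = 0.05
#: Spectra per lesion ("several hundred" per scan).
DEFAULT_N_SPECTRA = 300

#: Truth-label key in spectrum metadata.
TRUTH_KEY = "truth"
LOW_SNR_TRUTH = "LOW_SNR"

#: Per-diagnosis mixture of source templates.  The SK and CM mixes are
#: calibration choices placing the expected lesion score well below and
#: well above the malignancy cut-off respectively; real per-lesion spectral
#: compositions are unknown.
DEFAULT_TYPE_MIXES: dict[Diagnosis, dict[Phenotype, float]] = {
    Diagnosis.SK: {Phenotype.SK: 0.70, Phenotype.BACKGROUND: 0.20,
                   Phenotype.NEVUS: 0.08, Phenotype.CM: 0.02},
    Diagnosis.CM: {Phenotype.CM: 0.45, Phenotype.BACKGROUND: 0.40,
                   Phenotype.NEVUS: 0.15},
    Diagnosis.NEVUS: {Phenotype.NEVUS: 0.70, Phenotype.BACKGROUND: 0.25,
                      Phenotype.SK: 0.05},
}


@dataclass(frozen=True)
class LesionRecipe:
    """Parameters of one synthetic lesion."""

    diagnosis: Diagnosis = Diagnosis.SK
    n_spectra: int = DEFAULT_N_SPECTRA
    type_mix: dict[Phenotype, float] | None = None
    low_snr_fraction: float = DEFAULT_LOW_SNR_FRACTION
    noise_level: float = DEFAULT_NOISE_LEVEL
    counts_scale: float = DEFAULT_COUNTS_SCALE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be >= 1")
        if not 0.0 <= self.low_snr_fraction <= 1.0:
            raise ValueError("low_snr_fraction must be a probability")
        if self.noise_level < 0:
            raise ValueError("noise_level must be nonnegative")
        if self.counts_scale <= 0:
            raise ValueError("counts_scale must be positive")
        mix = self.resolved_mix()
        probs = np.array(list(mix.values()), dtype=float)
        if np.any(probs < 0) or np.any(probs > 1) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("type_mix probabilities must lie in [0,1] and sum to 1")

    def resolved_mix(self) -> dict[Phenotype, float]:
        if self.type_mix is not None:
            return {Phenotype(k): v for k, v in self.type_mix.items()}
        return dict(DEFAULT_TYPE_MIXES[self.diagnosis])


@dataclass(frozen=True)
class CohortRecipe:
    """Parameters of a synthetic cohort (defaults mirror the study: 28/5/24)."""

    n_sk: int = 28
    n_nevus: int = 5
    n_cm: int = 24
    n_spectra: int = DEFAULT_N_SPECTRA
    low_snr_fraction: float = DEFAULT_LOW_SNR_FRACTION
    noise_level: float = DEFAULT_NOISE_LEVEL
    counts_scale: float = DEFAULT_COUNTS_SCALE
    type_mixes: dict[Diagnosis, dict[Phenotype, float]] | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sk, self.n_nevus, self.n_cm) < 0:
            raise ValueError("cohort counts must be nonnegative")

    def mix_for(self, diagnosis: Diagnosis) -> dict[Phenotype, float] | None:
        if self.type_mixes is None:
            return None
        mix = self.type_mixes.get(diagnosis) or self.type_mixes.get(diagnosis.value)
        if mix is None:
            return None
        return {Phenotype(k): float(v) for k, v in mix.items()}


def generate_spectrum(
    template: Spectrum,
    noise_level: float,
    scale: float,
    rng: np.random.Generator,
    spectrum_id: str = "s0",
) -> Spectrum:
    """One noisy spectrum: ``scale * template`` plus count noise, clipped at 0."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    mean = scale * template.intensities
    sigma = noise_level * np.sqrt(mean + 1.0)
    values = np.clip(mean + rng.normal(0.0, 1.0, mean.shape) * sigma, 0.0, None)
    meta = {TRUTH_KEY: template.meta.get("phenotype", "TEMPLATE")}
    return Spectrum(template.grid, values, spectrum_id=spectrum_id,
                    stage=Stage.RAW, meta=meta)


def generate_low_snr_spectrum(
    rng: np.random.Generator,
    grid: WavelengthGrid | None = None,
    noise_counts: float = 1.0,
    spectrum_id: str = "s0",
) -> Spectrum:
    """A spectrum with (almost) no signal: detector noise around zero.

    Constructed so that the SNR estimate of the preprocessing stage falls
    below its default threshold with overwhelming probability.
    """
    grid = grid or make_default_grid()
    values = np.clip(rng.normal(0.0, noise_counts, grid.n_points), 0.0, None)
    return Spectrum(grid, values, spectrum_id=spectrum_id, stage=Stage.RAW,
                    meta={TRUTH_KEY: LOW_SNR_TRUTH})


def generate_lesion(
    recipe: LesionRecipe,
    lesion_id: str | None = None,
    templates: dict[Phenotype, Spectrum] | None = None,
) -> LesionScan:
    """Generate one synthetic lesion scan, deterministic given ``recipe.seed``.

    ``templates`` may override the default phenotype templates (config-driven
    pipelines pass composed templates here).
    """
    grid = make_default_grid()
    rng = np.random.default_rng(np.random.SeedSequence(recipe.seed))
    mix = recipe.resolved_mix()
    phenotypes = list(mix.keys())
    probs = np.array([mix[p] for p in phenotypes])
    templates = {
        p: (templates[p] if templates and p in templates else compose_template(p, grid))
        for p in phenotypes
    }

    choices = rng.choice(len(phenotypes), size=recipe.n_spectra, p=probs)
    low_snr = rng.random(recipe.n_spectra) < recipe.low_snr_fraction
    spectra = []
    for i in range(recipe.n_spectra):
        sid = f"s{i:04d}"
        if low_snr[i]:
            spectra.append(generate_low_snr_spectrum(rng, grid, spectrum_id=sid))
        else:
            spectra.append(
                generate_spectrum(templates[phenotypes[choices[i]]],
                                  recipe.noise_level, recipe.counts_scale,
                                  rng, spectrum_id=sid)
            )
    lesion_id = lesion_id or f"lesion_{recipe.diagnosis.value}_{recipe.seed}"
    return LesionScan(lesion_id, spectra, diagnosis=recipe.diagnosis,
                      meta={"seed": str(recipe.seed)})


def generate_cohort(
    recipe: CohortRecipe,
    templates: dict[Phenotype, Spectrum] | None = None,
) -> list[LesionScan]:
    """Generate a labeled cohort; lesion ``i`` is seeded by
    ``SeedSequence([master_seed, i])`` so two cohorts from one master seed
    are identical."""
    plan: list[Diagnosis] = (
        [Diagnosis.SK] * recipe.n_sk
        + [Diagnosis.NEVUS] * recipe.n_nevus
        + [Diagnosis.CM] * recipe.n_cm
    )
    lesions = []
    for i, diagnosis in enumerate(plan):
        seed = int(np.random.SeedSequence([recipe.master_seed, i]).generate_state(1)[0]
                   % (2**31))
        lesion_recipe = LesionRecipe(
            diagnosis=diagnosis,
            n_spectra=recipe.n_spectra,
            type_mix=recipe.mix_for(diagnosis),
            low_snr_fraction=recipe.low_snr_fraction,
            noise_level=recipe.noise_level,
            counts_scale=recipe.counts_scale,
            seed=seed,
        )
        lesions.append(generate_lesion(lesion_recipe,
                                       lesion_id=f"L{i:03d}_{diagnosis.value}",
                                       templates=templates))
    return lesions
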