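"""Seeded generative model of mass-photometry landing events.

The simulator emulates the contrast distributions an MP instrument records
for calibrant species, intact AAV samples and genome-release products.
The model is deliberately linear: every species lands with mean contrast
``-(coefficient x size) + drift``, plus per-event Gaussian noise.  Class
coefficients encode the empirical observation that different material
classes scatter differently per base:

* proteins, capsids and the HMW standard share ``alpha_capsid`` contrast
  per kDa;
* free single-stranded linear DNA (the released genome) contributes
  ``alpha_free_ss`` contrast per base;
* free RNA, circular ssDNA plasmids and dsDNA ladders contribute
  ``alpha_free_ss / class_ratio`` per base (per bp = 2 bases for dsDNA),
  so that sizing an encapsidated genome against those ladders
  *over*-estimates by the configured ratio;
* the genome confined inside a capsid scatters like protein mass scaled
  by the ``protein_mass_route`` ratio, so even the protein/mass route
  carries a small configurable bias.

Identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import constants
from .errors import ValidationError
from .events_io import ContrastMeasurement, SpeciesSpec

__all__ = [
    "SimConfig",
    "StudyFixture",
    "CALIBRANT_SPECIES",
    "species_coefficient",
    "simulate_species_events",
    "simulate_intact_aav_sample",
    "simulate_calibrant_set",
    "simulate_genome_release",
    "make_study_fixture",
]

#: Default over-estimation ratios per calibration family, matching the
#: observed intact-AAV sizing accuracies (RNA ~110 %, circular ssDNA
#: ~119 %, dsDNA ~147 %, mass route ~103 %).
DEFAULT_CLASS_RATIO: dict[str, float] = {
    "ssRNA": 1.10,
    "ssDNA_circular": 1.19,
    "dsDNA_per_2bases": 1.47,
    "protein_mass_route": 1.03,
}

DEFAULT_FRAGMENT_FRACTION = {"heat": 0.25, "sds": 0.05}
DEFAULT_AGGREGATE_FRACTION = {"heat": 0.05, "sds": 0.005}


@dataclass
class SimConfig:
    """Generative parameters of the landing-event simulator.

    Parameters
    ----------
    alpha_capsid : contrast per kDa for protein-class particles; the
        default ties the capsid mass route to the free-ssDNA anchor and
        places the 3,700 kDa empty capsid near -0.105 contrast.
    per_base_mass : kDa per base of encapsidated ssDNA (0.309).
    alpha_free_ss : contrast per base of free linear ssDNA, anchored to
        the released-genome peak at about -0.041 for 4,658 bases.
    class_ratio : per-family over-estimation factors (see module docs).
    sigma_event : per-event contrast noise SD.
    drift_sd : SD of the per-measurement additive contrast offset.
    n_per_peak : target landing events per population (~300 counts).
    fragment_fraction / aggregate_fraction : artifact event shares per
        genome-release workflow (uniform fragments below 0.030 contrast
        magnitude; aggregates at 0.5-1.0).
    intercept_contrast : optional global contrast offset (default 0) to
        exercise intercept-handling paths.
    seed : base seed; identical configs produce bit-identical events.
    """

    alpha_capsid: float = constants.ALPHA_CAPSID
    per_base_mass: float = constants.PER_BASE_MASS_KDA
    alpha_free_ss: float = constants.ALPHA_FREE_SS
    class_ratio: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_RATIO))
    sigma_event: float = 0.002
    drift_sd: float = 0.001
    n_per_peak: int = 300
    empty_capsid_mass: float = constants.EMPTY_CAPSID_MASS_KDA
    hmw_mass: float = constants.HMW_STANDARD_MASS_KDA
    fragment_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRAGMENT_FRACTION)
    )
    aggregate_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGGREGATE_FRACTION)
    )
    intercept_contrast: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_capsid", "per_base_mass", "alpha_free_ss"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name, value in self.class_ratio.items():
            if value <= 0:
                raise ValidationError(f"class_ratio[{name!r}] must be > 0")
        if self.sigma_event < 0 or self.drift_sd < 0:
            raise ValidationError("noise SDs must be >= 0")
        for d in (self.fragment_fraction, self.aggregate_fraction):
            for wf, frac in d.items():
                if not (0 <= frac < 1):
                    raise ValidationError(f"artifact fraction for {wf!r} must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def noiseless(self) -> "SimConfig":
        """Copy with event noise and drift switched off."""
        return replace(self, sigma_event=0.0, drift_sd=0.0)


def species_coefficient(material_class: str, cfg: SimConfig) -> float:
    """Contrast magnitude per size unit (kDa, base or bp) for a class."""
    if material_class in ("protein", "aav_capsid", "hmw_standard"):
        return cfg.alpha_capsid
    if material_class == "ssRNA":
        return cfg.alpha_free_ss / cfg.class_ratio["ssRNA"]
    if material_class == "ssDNA_circular":
        return cfg.alpha_free_ss / cfg.class_ratio["ssDNA_circular"]
    if material_class == "ssDNA_linear":
        return cfg.alpha_free_ss
    if material_class == "dsDNA":
        # per bp: two bases' worth of contrast, scaled by the dsDNA ratio
        return constants.BASES_PER_BP * cfg.alpha_free_ss / cfg.class_ratio["dsDNA_per_2bases"]
    raise ValidationError(f"unknown material class {material_class!r}")


def _finish(
    events: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    measurement_id: str,
    day_id: str,
    sample_id: str,
    metadata: dict | None = None,
) -> ContrastMeasurement:
    drift = rng.normal(0.0, cfg.drift_sd) if cfg.drift_sd > 0 else 0.0
    events = events + drift + cfg.intercept_contrast
    meta = {"drift": float(drift)}
    if metadata:
        meta.update(metadata)
    return ContrastMeasurement(
        measurement_id=measurement_id,
        events=events,
        day_id=day_id,
        sample_id=sample_id,
        metadata=meta,
        allow_empty=True,
    )


def simulate_species_events(
    spec: SpeciesSpec,
    n: int,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    measurement_id: str | None = None,
    day_id: str = "",
    sample_id: str | None = None,
) -> ContrastMeasurement:
    """Simulate one acquisition of a single calibrant species."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = rng if rng is not None else cfg.rng()
    mean = -species_coefficient(spec.material_class, cfg) * spec.size_value
    noise = rng.normal(0.0, cfg.sigma_event, size=n) if cfg.sigma_event > 0 else np.zeros(n)
    return _finish(
        np.full(n, mean) + noise,
        cfg,
        rng,
        measurement_id or f"{spec.name}_m0",
        day_id,
        sample_id if sample_id is not None else spec.name,
        metadata={"species": spec.name, "true_mean": float(mean)},
    )


def filled_capsid_mass(genome_length: float, cfg: SimConfig) -> float:
    """Apparent (optical) mass in kDa of a filled capsid.

    The encapsidated genome contributes its chain mass scaled by the
    ``protein_mass_route`` ratio, modelling the slightly different
    scattering of DNA confined in the capsid.
    """
    return cfg.empty_capsid_mass + (
        cfg.class_ratio["protein_mass_route"] * cfg.per_base_mass * genome_length
    )


def simulate_intact_aav_sample(
    genome_length: float,
    empty_fraction: float,
    n_total: int,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    hmw_fraction: float = 0.0,
    measurement_id: str = "aav_m0",
    day_id: str = "",
    sample_id: str = "",
) -> ContrastMeasurement:
    """Simulate an intact AAV acquisition: empty + filled capsid mixture.

    ``empty_fraction`` splits the non-HMW events between empty capsids
    (mass 3,700 kDa) and filled capsids (3,700 + ~0.309 kDa/base); an
    optional ``hmw_fraction`` of events comes from a spiked HMW standard.
    Event counts are multinomial.
    """
    if not (0 <= empty_fraction <= 1):
        raise ValidationError("empty_fraction must be in [0, 1]")
    if not (0 <= hmw_fraction < 1):
        raise ValidationError("hmw_fraction must be in [0, 1)")
    rng = rng if rng is not None else cfg.rng()
    p_empty = (1 - hmw_fraction) * empty_fraction
    p_filled = (1 - hmw_fraction) * (1 - empty_fraction)
    counts = rng.multinomial(n_total, [p_empty, p_filled, hmw_fraction])
    means = (
        -cfg.alpha_capsid * cfg.empty_capsid_mass,
        -cfg.alpha_capsid * filled_capsid_mass(genome_length, cfg),
        -cfg.alpha_capsid * cfg.hmw_mass,
    )
    parts = []
    for n_i, mean in zip(counts, means):
        noise = rng.normal(0.0, cfg.sigma_event, size=n_i) if cfg.sigma_event > 0 else 0.0
        parts.append(np.full(n_i, mean) + noise)
    return _finish(
        np.concatenate(parts),
        cfg,
        rng,
        measurement_id,
        day_id,
        sample_id,
        metadata={"genome_length": float(genome_length), "counts": [int(c) for c in counts]},
    )


def _species(name, cls, value, unit):
    return SpeciesSpec(name=name, material_class=cls, size_value=value, size_unit=unit)


#: Calibrant species per family: protein masses in kDa, dsDNA ladder in bp,
#: RNA ladder and circular ssDNA plasmids in bases.
CALIBRANT_SPECIES: dict[str, list[SpeciesSpec]] = {
    "protein_mass": [
        _species("urease_trimer", "protein", 272.0, "kDa"),
        _species("urease_hexamer", "protein", 545.0, "kDa"),
        _species("thyroglobulin", "protein", 670.0, "kDa"),
        _species("empty_aav", "aav_capsid", constants.EMPTY_CAPSID_MASS_KDA, "kDa"),
    ],
    "dsDNA_bp": [
        _species(f"dsDNA_{bp}bp", "dsDNA", float(bp), "bp")
        for bp in (100, 200, 400, 800, 1200, 2000)
    ],
    "RNA_bases": [
        _species(f"RNA_{b}b", "ssRNA", float(b), "bases")
        for b in (200, 500, 1000, 1500, 2000, 3000, 4000, 6000)
    ],
    "ssDNA_plasmid_bases": [
        _species("PhiX174_virion", "ssDNA_circular", 5386.0, "bases"),
        _species("M13_mp18", "ssDNA_circular", 7249.0, "bases"),
    ],
}


def simulate_calibrant_set(
    family: str,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    day_id: str = "",
) -> list[tuple[SpeciesSpec, ContrastMeasurement]]:
    """One acquisition of ``n_per_peak`` events per calibrant of a family."""
    if family not in CALIBRANT_SPECIES:
        raise ValidationError(f"unknown calibrant family {family!r}")
    rng = rng if rng is not None else cfg.rng()
    out = []
    for spec in CALIBRANT_SPECIES[family]:
        m = simulate_species_events(
            spec,
            cfg.n_per_peak,
            cfg,
            rng=rng,
            measurement_id=f"{family}:{spec.name}:{day_id or 'd0'}",
            day_id=day_id,
        )
        out.append((spec, m))
    return out


def simulate_genome_release(
    genome_length: float,
    workflow: str,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    n_total: int | None = None,
    measurement_id: str = "release_m0",
    day_id: str = "",
    sample_id: str = "",
) -> ContrastMeasurement:
    """Simulate an acquisition after capsid disassembly (no intact AAVs).

    Released-genome events land at ``-alpha_free_ss x genome_length``;
    fragment events are uniform in magnitude below 0.030 and aggregate
    events uniform in 0.5-1.0, with workflow-specific shares (the heat-only
    workflow produces markedly more of both than heat + SDS removal).
    """
    if workflow not in cfg.fragment_fraction or workflow not in cfg.aggregate_fraction:
        raise ValidationError(f"unknown release workflow {workflow!r}")
    rng = rng if rng is not None else cfg.rng()
    f_frag = cfg.fragment_fraction[workflow]
    f_agg = cfg.aggregate_fraction[workflow]
    if n_total is None:
        # keep the genome peak itself near n_per_peak counts
        n_total = int(round(cfg.n_per_peak / (1 - f_frag - f_agg)))
    n_frag, n_agg, n_genome = rng.multinomial(n_total, [f_frag, f_agg, 1 - f_frag - f_agg])
    mean = -cfg.alpha_free_ss * genome_length
    noise = rng.normal(0.0, cfg.sigma_event, size=n_genome) if cfg.sigma_event > 0 else 0.0
    genome_ev = np.full(n_genome, mean) + noise
    frag_ev = -rng.uniform(0.0, 0.030, size=n_frag)
    agg_ev = -rng.uniform(0.5, 1.0, size=n_agg)
    return _finish(
        np.concatenate([genome_ev, frag_ev, agg_ev]),
        cfg,
        rng,
        measurement_id,
        day_id,
        sample_id,
        metadata={
            "workflow": workflow,
            "genome_length": float(genome_length),
            "counts": {"genome": int(n_genome), "fragment": int(n_frag), "aggregate": int(n_agg)},
        },
    )


@dataclass
class StudyFixture:
    """A full simulated study: calibrants, intact samples and release runs.

    Keys of ``calibrants`` are ``(day_id, family)``; keys of ``intact`` and
    ``release`` are ``(day_id, sample_id)`` with one measurement per
    replicate.
    """

    expected: dict[str, float]
    calibrants: dict[tuple[str, str], list[tuple[SpeciesSpec, ContrastMeasurement]]]
    intact: dict[tuple[str, str], list[ContrastMeasurement]]
    release: dict[tuple[str, str], list[ContrastMeasurement]]
    config: SimConfig

    @property
    def day_ids(self) -> list[str]:
        return sorted({day for day, _ in self.intact})

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.expected)


def make_study_fixture(
    cfg: SimConfig,
    n_days: int = 3,
    reps_per_day: int = 3,
    empty_fraction: float = 0.5,
    families: tuple[str, ...] = ("protein_mass", "dsDNA_bp", "RNA_bases", "ssDNA_plasmid_bases"),
    release_workflow: str = "sds",
) -> StudyFixture:
    """Simulate the full three-day study design.

    Per day: one calibrant acquisition set per family, ``reps_per_day``
    intact acquisitions of each of the five AAV samples (each spiked with
    empty capsids), and ``reps_per_day`` genome-release acquisitions per
    sample.  Deterministic for a given config/seed.
    """
    rng = cfg.rng()
    expected = dict(constants.STUDY_GENOME_LENGTHS)
    calibrants: dict = {}
    intact: dict = {}
    release: dict = {}
    for d in range(n_days):
        day = f"day{d + 1}"
        for family in families:
            calibrants[(day, family)] = simulate_calibrant_set(family, cfg, rng=rng, day_id=day)
        for sample, length in expected.items():
            intact[(day, sample)] = [
                simulate_intact_aav_sample(
                    length,
                    empty_fraction,
                    2 * cfg.n_per_peak,
                    cfg,
                    rng=rng,
                    measurement_id=f"{sample}:{day}:r{r + 1}",
                    day_id=day,
                    sample_id=sample,
                )
                for r in range(reps_per_day)
            ]
            release[(day, sample)] = [
                simulate_genome_release(
                    length,
                    release_workflow,
                    cfg,
                    rng=rng,
                    measurement_id=f"{sample}:release:{day}:r{r + 1}",
                    day_id=day,
                    sample_id=sample,
                )
                for r in range(reps_per_day)
            ]
    return StudyFixture(
        expected=expected,
        calibrants=calibrants,
        intact=intact,
        release=release,
        config=cfg,
    )
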