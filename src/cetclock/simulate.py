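"""Synthetic multi-species methylation panels with planted age and sex signal.

The generator emulates the structure of a pooled cetacean methylation
dataset assembled from mammalian-array studies: 13 species sampled in two
tissues (blood and skin), chronological ages spanning 0-139 years with
per-species lifespan differences, a fraction of CpGs whose mean beta moves
monotonically with (transformed) age — shared across species or re-drawn
per species — and sex-differential CpGs concentrated on a designated sex
chromosome. Noise is i.i.d. Gaussian on the beta scale with clamping to
[0, 1]; probe-level chemistry, batch effects and cross-hybridization are
deliberately not modelled.

Planted age CpG ``i`` in species ``s`` has mean beta

    squash(b0_{i,s} + m_{i,s} * f(age))

where ``f`` is the package age transform, ``m_{i,s}`` the slope on the
transformed-age scale (equal to the shared ``m_i`` for the shared-effect
fraction of CpGs, independently re-drawn otherwise), ``b0_{i,s}`` a
species-shifted baseline, and ``squash`` a clamp to [0.001, 0.999].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .transform import TransformSpec, transform_age
from .types import BetaMatrix, CpGMap, RegionSet, SamplePanel, ValidationError

SEX_CHROMOSOME = "chrX_sim"
_AUTOSOMES = [f"chr{i}" for i in range(1, 22)]


@dataclass
class SimulationScenario:
    """Parameters of a synthetic multi-species methylation study.

    Defaults mirror the pooled cetacean dataset the package targets:
    13 species, blood (22 per species, 286 total) and skin (62 per species),
    maximum lifespans spanning ~25-139 years, and the full ~37k-CpG
    mammalian array.
    """

    n_species: int = 13
    max_lifespan_years: Sequence[float] | None = None
    samples_per_stratum: int | Mapping[str, int] = field(
        default_factory=lambda: {"blood": 22, "skin": 62}
    )
    tissues: tuple[str, ...] = ("blood", "skin")
    n_cpgs: int = 37000
    n_age_cpgs: int = 3700
    n_sex_cpgs: int = 370
    slope_mean: float = 0.06  # |slope| on the transformed-age scale
    slope_sd: float = 0.02
    baseline_low: float = 0.1
    baseline_high: float = 0.9
    species_baseline_sd: float = 0.03
    sex_effect_size: float = 0.1  # |delta beta| added for females
    noise_sd: float = 0.03
    shared_effect_fraction: float = 1.0
    age_skew_power: float = 1.0  # 1 = uniform ages; >1 skews young
    transform: TransformSpec = field(default_factory=TransformSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_species, self.n_cpgs, self.n_age_cpgs, self.n_sex_cpgs]
        if any(c < 0 for c in counts):
            raise ValidationError("scenario counts must be >= 0")
        if self.n_age_cpgs + self.n_sex_cpgs > self.n_cpgs:
            raise ValidationError("n_age_cpgs + n_sex_cpgs exceeds n_cpgs")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 <= self.shared_effect_fraction <= 1:
            raise ValidationError("shared_effect_fraction must be in [0, 1]")
        if self.age_skew_power <= 0:
            raise ValidationError("age_skew_power must be > 0")
        if self.max_lifespan_years is None:
            self.max_lifespan_years = tuple(
                np.round(np.linspace(25.0, 139.0, self.n_species), 1)
            )
        if len(self.max_lifespan_years) != self.n_species:
            raise ValidationError("max_lifespan_years length must equal n_species")
        if any(l <= 0 for l in self.max_lifespan_years):
            raise ValidationError("lifespans must be positive")

    def stratum_size(self, tissue: str) -> int:
        if isinstance(self.samples_per_stratum, Mapping):
            return int(self.samples_per_stratum[tissue])
        return int(self.samples_per_stratum)


def standard_scenario(seed: int = 42, **overrides) -> SimulationScenario:
    """The compact recovery scenario used throughout the test battery:
    6 species x 2 tissues x 40 samples, 2,000 CpGs, 200 planted age CpGs,
    20 planted sex CpGs, fully shared age effects."""
    kwargs = dict(
        n_species=6,
        samples_per_stratum=40,
        n_cpgs=2000,
        n_age_cpgs=200,
        n_sex_cpgs=20,
        shared_effect_fraction=1.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationScenario(**kwargs)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    age_cpgs: dict[str, float]  # cpg_id -> shared (or mean) signed slope
    sex_cpgs: dict[str, float]  # cpg_id -> signed female effect on beta
    sex_chromosome: str
    true_ages: pd.Series  # sample_id -> age (years)

    def __post_init__(self) -> None:
        if set(self.age_cpgs) & set(self.sex_cpgs):
            raise ValidationError("planted age and sex CpG sets must be disjoint")

    @property
    def positive_age_cpgs(self) -> list[str]:
        return [c for c, m in self.age_cpgs.items() if m > 0]

    @property
    def negative_age_cpgs(self) -> list[str]:
        return [c for c, m in self.age_cpgs.items() if m < 0]


def _species_names(n: int) -> list[str]:
    return [f"species_{i + 1:02d}" for i in range(n)]


def generate_panel(
    scenario: SimulationScenario,
) -> tuple[SamplePanel, BetaMatrix, CpGMap, GroundTruth]:
    """Generate a full synthetic study; bit-identical for a fixed seed."""
    rng = np.random.default_rng(scenario.seed)
    sc = scenario
    species = _species_names(sc.n_species)

    # --- samples -----------------------------------------------------------
    sample_id: list[str] = []
    sp_col: list[str] = []
    ti_col: list[str] = []
    ages: list[float] = []
    sexes: list[str] = []
    for si, sp in enumerate(species):
        lifespan = float(sc.max_lifespan_years[si])
        for tissue in sc.tissues:
            n = sc.stratum_size(tissue)
            u = rng.uniform(size=n)
            a = lifespan * u ** sc.age_skew_power
            sex = rng.choice(["F", "M"], size=n)
            for j in range(n):
                sample_id.append(f"{sp}_{tissue}_{j + 1:03d}")
                sp_col.append(sp)
                ti_col.append(tissue)
                ages.append(float(a[j]))
                sexes.append(str(sex[j]))
    panel = SamplePanel(
        sample_id=sample_id,
        species=sp_col,
        tissue=ti_col,
        age_years=np.asarray(ages),
        sex=sexes,
        age_known=[True] * len(sample_id),
    )
    n_samples = len(panel)
    f_age = transform_age(panel.age_years, sc.transform)
    species_idx = np.asarray([species.index(s) for s in panel.species])
    female = np.asarray([s == "F" for s in panel.sex], dtype=float)

    # --- CpG identities and positions --------------------------------------
    cpg_ids = [f"cg{i:06d}" for i in range(sc.n_cpgs)]
    planted = rng.choice(sc.n_cpgs, size=sc.n_age_cpgs + sc.n_sex_cpgs, replace=False)
    age_idx = np.sort(planted[: sc.n_age_cpgs])
    sex_idx = np.sort(planted[sc.n_age_cpgs :])
    chroms = np.asarray(rng.choice(_AUTOSOMES, size=sc.n_cpgs), dtype=object)
    chroms[sex_idx] = SEX_CHROMOSOME
    # strictly increasing positions within each chromosome
    positions = np.empty(sc.n_cpgs, dtype=np.int64)
    for chrom in set(chroms.tolist()):
        mask = chroms == chrom
        positions[mask] = np.cumsum(rng.integers(200, 5000, size=mask.sum())) + 1
    cpg_map = CpGMap(
        pd.DataFrame({"cpg_id": cpg_ids, "chromosome": chroms, "position": positions})
    )

    # --- mean beta surface ---------------------------------------------------
    base = rng.uniform(sc.baseline_low, sc.baseline_high, size=sc.n_cpgs)
    mean = np.tile(base, (n_samples, 1))

    sign = rng.choice([-1.0, 1.0], size=sc.n_age_cpgs)
    mag = np.abs(rng.normal(sc.slope_mean, sc.slope_sd, size=sc.n_age_cpgs))
    slopes = sign * mag
    shared = rng.uniform(size=sc.n_age_cpgs) < sc.shared_effect_fraction
    # per-species slopes: shared CpGs reuse the base slope; others re-draw
    per_species = np.tile(slopes, (sc.n_species, 1))
    if (~shared).any():
        redraw_sign = rng.choice([-1.0, 1.0], size=(sc.n_species, (~shared).sum()))
        redraw_mag = np.abs(
            rng.normal(sc.slope_mean, sc.slope_sd, size=(sc.n_species, (~shared).sum()))
        )
        per_species[:, ~shared] = redraw_sign * redraw_mag
    # baselines that leave headroom for the age trend before clamping
    lo = np.where(slopes > 0, 0.1, 0.4)
    hi = np.where(slopes > 0, 0.6, 0.9)
    base_age = rng.uniform(lo, hi)
    sp_shift = rng.normal(0.0, sc.species_baseline_sd, size=(sc.n_species, sc.n_age_cpgs))
    mean[:, age_idx] = (
        base_age[None, :]
        + sp_shift[species_idx]
        + per_species[species_idx] * f_age[:, None]
    )

    sex_sign = rng.choice([-1.0, 1.0], size=sc.n_sex_cpgs)
    sex_delta = sex_sign * sc.sex_effect_size
    mean[:, sex_idx] = (
        rng.uniform(0.2, 0.8, size=sc.n_sex_cpgs)[None, :]
        + female[:, None] * sex_delta[None, :]
    )

    np.clip(mean, 0.001, 0.999, out=mean)
    values = mean + rng.normal(0.0, sc.noise_sd, size=mean.shape)
    np.clip(values, 0.0, 1.0, out=values)
    betas = BetaMatrix(sample_ids=list(sample_id), cpg_ids=cpg_ids, values=values)

    truth = GroundTruth(
        age_cpgs={cpg_ids[i]: float(s) for i, s in zip(age_idx, slopes)},
        sex_cpgs={cpg_ids[i]: float(d) for i, d in zip(sex_idx, sex_delta)},
        sex_chromosome=SEX_CHROMOSOME,
        true_ages=pd.Series(panel.age_years, index=panel.sample_id, name="age_years"),
    )
    return panel, betas, cpg_map, truth


def generate_annotation_fixture(
    truth: GroundTruth,
    cpg_map: CpGMap,
    enrichment_factor: float = 5.0,
    seed: int = 0,
    background_rate: float = 0.08,
) -> list[RegionSet]:
    """Mock annotation region sets for the enrichment analyses.

    Emits mock chromatin states (one, ``BivProm_sim``, enriched for planted
    positive-age CpGs at ``enrichment_factor`` times the background
    inclusion rate, plus null states), mock TF peak datasets (an enriched
    TF with two datasets and a null TF), and mock PRC2 member peak sets
    (EED/SUZ12/EZH2 enriched, so the two-member rule captures the planted
    CpGs) alongside a lone background PRC1 member.
    """
    if enrichment_factor < 1:
        raise ValidationError("enrichment_factor must be >= 1")
    rng = np.random.default_rng(seed)
    pos_cpgs = set(truth.positive_age_cpgs)
    tab = cpg_map.table
    is_pos = tab["cpg_id"].isin(pos_cpgs).to_numpy()
    p_inc = np.where(
        is_pos, min(1.0, enrichment_factor * background_rate), background_rate
    )

    def draw_set(name: str, rate_mask=None, source: str | None = None) -> RegionSet:
        probs = p_inc if rate_mask is None else np.full(len(tab), background_rate)
        take = rng.uniform(size=len(tab)) < probs
        intervals = []
        widths = rng.integers(20, 200, size=int(take.sum()))
        for (chrom, pos), w in zip(
            tab.loc[take, ["chromosome", "position"]].itertuples(index=False), widths
        ):
            intervals.append((chrom, max(0, int(pos) - 1 - int(w)), int(pos) + int(w)))
        return RegionSet(name, intervals, source_label=source)

    sets = [
        draw_set("BivProm_sim"),
        draw_set("Quies_sim", rate_mask="null"),
        draw_set("Enh_sim", rate_mask="null"),
        draw_set("TxEx_sim", rate_mask="null"),
        draw_set("TF_AGE_sim", source="dataset_1"),
        draw_set("TF_AGE_sim", source="dataset_2"),
        draw_set("TF_NULL_sim", rate_mask="null", source="dataset_1"),
        draw_set("EED_sim"),
        draw_set("SUZ12_sim"),
        draw_set("EZH2_sim"),
        draw_set("RING1_sim", rate_mask="null"),
    ]
    return sets
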