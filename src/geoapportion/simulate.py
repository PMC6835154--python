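"""Forward simulator for a multi-farm cage system with known ground truth.

Latent producer densities are drawn lognormally per fish and compartment
(mean-preserving parameterization, so sigma = 0 reproduces the configured
means exactly). Flesh geosmin follows a linear two-route mixture: an
intestinal route scaled by an uptake fraction, plus a water route
proportional to dissolved geosmin. All observables (qPCR plate, OTU
table, measurements) derive from these latents with the configured noise,
and the latents themselves are recorded as truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from geoapportion.massbalance import CellYield, NG_PER_G, ML_PER_L, PG_PER_G
from geoapportion.qpcr import GEOA_GROUPS, StandardCurve

#: Native density unit per compartment and the extract size used per sample.
SAMPLED_SIZES = {"water": 1.0, "mucous": 9.0, "digesta": 0.25, "fin": 9.0}
SAMPLE_UNITS = {"water": "mL", "mucous": "cm2", "digesta": "g", "fin": "cm2"}

#: Fixed split of producer gene copies across the four group assays.
GROUP_WEIGHTS = {"g1": 0.4, "g3": 0.3, "g4": 0.2, "g5": 0.1}

PRODUCER_LINEAGES = {
    "Actinomycetales": ("Bacteria", "Actinobacteria", "Actinobacteria", "Actinomycetales", "", ""),
    "Cyanobacteria": ("Bacteria", "Cyanobacteria", "", "", "", ""),
    "Myxococcales": ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Myxococcales", "", ""),
    "Sorangium": (
        "Bacteria",
        "Proteobacteria",
        "Deltaproteobacteria",
        "Myxococcales",
        "Polyangiaceae",
        "Sorangium",
    ),
}

_BACKGROUND_LINEAGES = (
    ("Bacteria", "Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae", "Cetobacterium"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae", ""),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", "Clostridium"),
    ("Bacteria", "Proteobacteria", "Betaproteobacteria", "", "", ""),
)


@dataclass(frozen=True)
class DensitySpec:
    """Lognormal latent density: mean in copies per native unit, log-sd sigma."""

    mean: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean) or self.mean < 0:
            raise ValueError(f"density mean must be finite and >= 0, got {self.mean}")
        if not math.isfinite(self.sigma) or self.sigma < 0:
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma}")


def _default_producer_density() -> dict[str, DensitySpec]:
    return {
        "water": DensitySpec(500.0, 0.5),
        "mucous": DensitySpec(2.0e5, 0.5),
        "digesta": DensitySpec(1.5e3, 0.5),
        "fin": DensitySpec(8.0e4, 0.5),
    }


def _default_total16s_density() -> dict[str, DensitySpec]:
    return {
        "water": DensitySpec(2.0e5, 0.5),
        "mucous": DensitySpec(1.0e8, 0.5),
        "digesta": DensitySpec(7.0e5, 0.5),
        "fin": DensitySpec(4.0e7, 0.5),
    }


def _default_clade_fractions() -> dict[str, float]:
    return {
        "Actinomycetales": 0.5,
        "Cyanobacteria": 0.35,
        "Myxococcales": 0.1,
        "Sorangium": 0.05,
    }


@dataclass
class SimConfig:
    """Parameters of the simulated cage system.

    A single ``seed`` fixes all downstream randomness; per-stage
    substreams are derived from it deterministically.
    """

    n_farms: int = 6
    fish_per_farm: int = 10
    compartments: tuple[str, ...] = ("water", "mucous", "digesta", "fin")
    producer_density: dict[str, DensitySpec] = field(default_factory=_default_producer_density)
    total16s_density: dict[str, DensitySpec] = field(default_factory=_default_total16s_density)
    yield_free: float = 73e-18
    yield_bound: float = 67e-18
    uptake_fraction: float = 0.3
    fish_mass_kg: float = 1.0
    mucous_area_cm2: float = 3075.0
    digesta_mass_g: float = 5.0
    water_route_coeff: float = 100.0  # ng/kg flesh per ng/L dissolved
    water_background_ng_per_l: float = 2.0
    cq_noise_sd: float = 0.0
    measurement_noise_rel: float = 0.0
    otu_depth: int = 20000
    n_background_otus: int = 46
    producer_clade_fractions: dict[str, float] = field(default_factory=_default_clade_fractions)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_farms < 1 or self.fish_per_farm < 1:
            raise ValueError("n_farms and fish_per_farm must be >= 1")
        if not self.compartments:
            raise ValueError("at least one compartment is required")
        unknown = set(self.compartments) - set(SAMPLED_SIZES)
        if unknown:
            raise ValueError(f"unknown compartments: {sorted(unknown)}")
        for m in (self.producer_density, self.total16s_density):
            for comp in self.compartments:
                if comp not in m:
                    raise ValueError(f"missing density spec for compartment {comp!r}")
        for v in (
            self.yield_free,
            self.yield_bound,
            self.fish_mass_kg,
            self.mucous_area_cm2,
            self.digesta_mass_g,
            self.water_route_coeff,
            self.water_background_ng_per_l,
            self.cq_noise_sd,
            self.measurement_noise_rel,
        ):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"config values must be finite and >= 0, got {v}")
        if self.fish_mass_kg <= 0 or self.mucous_area_cm2 <= 0:
            raise ValueError("fish mass and mucous area must be positive")
        if not 0.0 <= self.uptake_fraction <= 1.0:
            raise ValueError("uptake_fraction must lie in [0, 1]")
        if self.otu_depth < 1:
            raise ValueError("otu_depth must be >= 1")
        if self.n_background_otus < 1:
            raise ValueError("need at least one background OTU")

    @property
    def cell_yield(self) -> CellYield:
        return CellYield(self.yield_free, self.yield_bound)


@dataclass
class SyntheticDataset:
    """Observables plus the latent truth that generated them."""

    qpcr_plate: pd.DataFrame
    samples: pd.DataFrame
    otu_table: pd.DataFrame
    taxonomy: pd.DataFrame
    measurements: pd.DataFrame
    truth: dict

    def __post_init__(self) -> None:
        known = set(self.samples["sample_id"])
        orphans = set(self.otu_table.columns) - known
        if orphans:
            raise ValueError(f"OTU-table samples without metadata: {sorted(orphans)}")


def _lognormal_mean_preserving(rng: np.random.Generator, mean: float, sigma: float, size) -> np.ndarray:
    """Draws with E[X] = mean exactly; degenerate at sigma = 0."""
    if mean == 0.0:
        return np.zeros(size)
    if sigma == 0.0:
        return np.full(size, mean)
    return rng.lognormal(math.log(mean) - sigma**2 / 2.0, sigma, size)


def default_standard_curve() -> StandardCurve:
    """Perfect-doubling reference chemistry used by the simulator."""
    return StandardCurve(slope=-3.3219, intercept=40.0, r2=1.0)


def simulate_qpcr_plate(
    quantities: Mapping[str, float],
    curve: StandardCurve,
    noise_sd: float,
    replicates: int = 3,
    *,
    assay_id: str = "assay",
    rng: np.random.Generator | None = None,
    standard_series: Sequence[float] = tuple(10.0**k for k in range(1, 8)),
    standard_replicates: int = 3,
) -> pd.DataFrame:
    """Wells for one assay: a standard dilution series plus unknowns.

    Cq = intercept + slope*log10(copies) + Normal(0, noise_sd). Samples
    with fewer than one copy per reaction emit no-amplification wells
    (Cq = NaN).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for copies in standard_series:
        for rep in range(1, standard_replicates + 1):
            cq = curve.cq_of(copies) + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            rows.append(
                {
                    "sample_id": f"std_{copies:.0e}",
                    "assay_id": assay_id,
                    "replicate": rep,
                    "cq": cq,
                    "is_standard": True,
                    "standard_copies": copies,
                }
            )
    for sample_id, copies in quantities.items():
        if copies < 0:
            raise ValueError(f"negative copies for sample {sample_id}")
        for rep in range(1, replicates + 1):
            if copies < 1.0:
                cq = float("nan")  # below one copy per reaction: no amplification
            else:
                cq = curve.cq_of(copies) + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            rows.append(
                {
                    "sample_id": sample_id,
                    "assay_id": assay_id,
                    "replicate": rep,
                    "cq": cq,
                    "is_standard": False,
                    "standard_copies": float("nan"),
                }
            )
    return pd.DataFrame(rows)


def simulate_otu_table(
    base_composition: Sequence[float],
    producer_fraction: Sequence[float] | float,
    depth: int,
    n_samples: int | None = None,
    seed: int | np.random.Generator = 0,
    *,
    concentration: float = math.inf,
    producer_clade_fractions: Mapping[str, float] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dirichlet-multinomial OTU counts with embedded producer clades.

    Per sample the producer clades receive ``producer_fraction`` of the
    expected composition (split by clade weights) and the background is
    renormalized to the remainder. ``concentration = inf`` disables
    overdispersion (plain multinomial sampling).

    Returns (otu_table with OTUs as rows and samples as columns,
    taxonomy frame with otu_id and semicolon-joined lineage).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    base = np.asarray(base_composition, dtype=float)
    if base.ndim != 1 or base.size < 1:
        raise ValueError("base_composition must be a non-empty vector")
    if not math.isclose(base.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("base_composition must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pf = np.atleast_1d(np.asarray(producer_fraction, dtype=float))
    if n_samples is None:
        n_samples = pf.size
    if pf.size == 1:
        pf = np.full(n_samples, pf[0])
    if pf.size != n_samples:
        raise ValueError("producer_fraction length must match n_samples")
    if np.any((pf < 0) | (pf >= 1)):
        raise ValueError("producer_fraction must lie in [0, 1)")

    clades = producer_clade_fractions or _default_clade_fractions()
    clade_names = list(clades)
    w = np.asarray([clades[c] for c in clade_names], dtype=float)
    w = w / w.sum()

    otu_ids = [f"OTU_p{i + 1}" for i in range(len(clade_names))] + [
        f"OTU_b{i + 1}" for i in range(base.size)
    ]
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    counts = np.zeros((len(otu_ids), n_samples), dtype=int)
    for j in range(n_samples):
        target = np.concatenate([pf[j] * w, (1.0 - pf[j]) * base])
        if math.isfinite(concentration):
            if concentration <= 0:
                raise ValueError("concentration must be positive")
            alpha = np.maximum(concentration * target, 1e-12)
            p = rng.dirichlet(alpha)
        else:
            p = target
        counts[:, j] = rng.multinomial(depth, p)
    otu_table = pd.DataFrame(counts, index=otu_ids, columns=list(sample_ids))
    otu_table.index.name = "otu_id"

    lineages = [PRODUCER_LINEAGES[c] for c in clade_names] + [
        _BACKGROUND_LINEAGES[i % len(_BACKGROUND_LINEAGES)] for i in range(base.size)
    ]
    taxonomy = pd.DataFrame(
        {"otu_id": otu_ids, "lineage": [";".join(l).rstrip(";") for l in lineages]}
    )
    return otu_table, taxonomy


def simulate_farm_system(config: SimConfig) -> SyntheticDataset:
    """Generate the complete observable bundle for one cage system.

    Water is sampled once per farm; mucous, digesta and fin once per
    fish. Flesh geosmin per fish is

    ``uptake_fraction * (mucous cells + digesta cells) * yield / fish_mass
    + water_route_coeff * water_geosmin``

    and farm-level measurements report the mean with the SEM across fish.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_latent, rng_cq, rng_otu, rng_meas = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    curve = default_standard_curve()
    y_total = config.cell_yield.total_g_per_cell

    sample_rows = []
    latent_rows = []
    quantities_geoa: dict[str, float] = {}
    quantities_16s: dict[str, float] = {}

    def add_sample(sid: str, farm: int, fish: int | None, comp: str, d_prod: float, d_tot: float):
        size = SAMPLED_SIZES[comp]
        sample_rows.append(
            {
                "sample_id": sid,
                "farm": farm,
                "fish": fish if fish is not None else -1,
                "compartment": comp,
                "sampled_size": size,
                "unit": SAMPLE_UNITS[comp],
            }
        )
        latent_rows.append(
            {
                "sample_id": sid,
                "farm": farm,
                "compartment": comp,
                "producer_density": d_prod,
                "total16s_density": d_tot,
            }
        )
        quantities_geoa[sid] = d_prod * size
        quantities_16s[sid] = d_tot * size

    farm_water_density = {}
    farm_fish_latents: dict[int, dict[str, np.ndarray]] = {}
    for farm in range(1, config.n_farms + 1):
        farm_fish_latents[farm] = {}
        if "water" in config.compartments:
            spec = config.producer_density["water"]
            tspec = config.total16s_density["water"]
            d = float(_lognormal_mean_preserving(rng_latent, spec.mean, spec.sigma, 1)[0])
            t = float(_lognormal_mean_preserving(rng_latent, tspec.mean, tspec.sigma, 1)[0])
            farm_water_density[farm] = d
            add_sample(f"f{farm}_water", farm, None, "water", d, t)
        for comp in config.compartments:
            if comp == "water":
                continue
            spec = config.producer_density[comp]
            tspec = config.total16s_density[comp]
            d = _lognormal_mean_preserving(rng_latent, spec.mean, spec.sigma, config.fish_per_farm)
            t = _lognormal_mean_preserving(rng_latent, tspec.mean, tspec.sigma, config.fish_per_farm)
            farm_fish_latents[farm][comp] = d
            for i in range(config.fish_per_farm):
                add_sample(f"f{farm}_fish{i + 1:02d}_{comp}", farm, i + 1, comp, float(d[i]), float(t[i]))

    # qPCR plate: geoA split across group assays plus the total-16S assay
    plates = []
    for g in GEOA_GROUPS:
        q = {sid: GROUP_WEIGHTS[g] * v for sid, v in quantities_geoa.items()}
        plates.append(
            simulate_qpcr_plate(q, curve, config.cq_noise_sd, assay_id=g, rng=rng_cq)
        )
    plates.append(
        simulate_qpcr_plate(quantities_16s, curve, config.cq_noise_sd, assay_id="16s", rng=rng_cq)
    )
    qpcr_plate = pd.concat(plates, ignore_index=True)

    samples = pd.DataFrame(sample_rows)
    latents = pd.DataFrame(latent_rows)

    # measurements: water geosmin per farm, flesh geosmin per farm (mean +- SEM)
    meas_rows = []
    truth_contribution = {}
    truth_water = {}
    truth_flesh = {}
    for farm in range(1, config.n_farms + 1):
        d_w = farm_water_density.get(farm, 0.0)
        water_calc = d_w * ML_PER_L * y_total * NG_PER_G
        water_true = config.water_background_ng_per_l + water_calc
        truth_water[farm] = water_true

        mucous_d = farm_fish_latents[farm].get("mucous", np.zeros(config.fish_per_farm))
        digesta_d = farm_fish_latents[farm].get("digesta", np.zeros(config.fish_per_farm))
        mucous_cells = mucous_d * config.mucous_area_cm2
        digesta_cells = digesta_d * config.digesta_mass_g
        intestinal_ng = (mucous_cells + digesta_cells) * y_total * NG_PER_G
        flesh_fish = (
            config.uptake_fraction * intestinal_ng / config.fish_mass_kg
            + config.water_route_coeff * water_true
        )
        if config.measurement_noise_rel > 0:
            flesh_fish = flesh_fish * (
                1.0 + rng_meas.normal(0, config.measurement_noise_rel, flesh_fish.shape)
            )
            water_obs = water_true * (1.0 + rng_meas.normal(0, config.measurement_noise_rel))
        else:
            water_obs = water_true
        flesh_mean = float(np.mean(flesh_fish))
        flesh_sem = (
            float(np.std(flesh_fish, ddof=1) / math.sqrt(len(flesh_fish)))
            if len(flesh_fish) > 1
            else 0.0
        )
        truth_flesh[farm] = flesh_mean
        meas_rows.append(
            {"farm": farm, "compartment": "water", "value": water_obs, "se": 0.0, "unit": "ng/L"}
        )
        meas_rows.append(
            {"farm": farm, "compartment": "flesh", "value": flesh_mean, "se": flesh_sem, "unit": "ng/kg"}
        )
        # uptake-free potential: what the mucous producers could supply at 100% release
        mucous_prod = float(np.mean(mucous_cells)) * y_total * NG_PER_G
        truth_contribution[farm] = (
            100.0 * mucous_prod / (flesh_mean * config.fish_mass_kg) if flesh_mean > 0 else float("nan")
        )
    measurements = pd.DataFrame(meas_rows)

    # OTU tables for mucous samples; producer fraction tracks the latent ratio
    mucous_samples = samples[samples["compartment"] == "mucous"]["sample_id"].tolist()
    lat = latents.set_index("sample_id")
    pf = np.array(
        [
            min(
                lat.loc[s, "producer_density"] / lat.loc[s, "total16s_density"]
                if lat.loc[s, "total16s_density"] > 0
                else 0.0,
                0.999,
            )
            for s in mucous_samples
        ]
    )
    base = np.full(config.n_background_otus, 1.0 / config.n_background_otus)
    otu_table, taxonomy = simulate_otu_table(
        base,
        pf,
        config.otu_depth,
        len(mucous_samples),
        rng_otu,
        producer_clade_fractions=config.producer_clade_fractions,
        sample_ids=mucous_samples,
    )

    truth = {
        "latents": latents,
        "yield_free": config.yield_free,
        "yield_bound": config.yield_bound,
        "uptake_fraction": config.uptake_fraction,
        "water_geosmin": truth_water,
        "flesh_geosmin": truth_flesh,
        "mucous_contribution_pct": truth_contribution,
        "curve": curve,
        "group_weights": dict(GROUP_WEIGHTS),
    }
    return SyntheticDataset(
        qpcr_plate=qpcr_plate,
        samples=samples,
        otu_table=otu_table,
        taxonomy=taxonomy,
        measurements=measurements,
        truth=truth,
    )
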