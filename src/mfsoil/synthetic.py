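"""Synthetic study-shaped data with known ground truth.

Emulates a replicated silvicultural microcosm survey: a complete block design
of mechanical site-preparation (MSP) treatments plus an unlogged reference,
replicate soil samples pooled into one composite per plot, composite-level
biogeochemical profiles, first-order trace-gas decay curves, and OTU count
tables carrying a shared dominant community plus class-restricted
rare-biosphere indicator OTUs.

Every generator is a pure function of its arguments and a seed; one global
seed expands to per-generator child seeds through ``numpy.random.SeedSequence``
spawn keys (see :func:`child_rng`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "PlantedCommunity",
    "DEFAULT_TREATMENTS",
    "DEFAULT_TREATMENT_PARAMS",
    "VARIABLE_BOUNDS",
    "BIOGEOCHEM_VARIABLES",
    "child_rng",
    "generate_design",
    "generate_biogeochem",
    "make_class_offsets",
    "generate_classed_biogeochem",
    "generate_gas_timeseries",
    "generate_otu_table",
    "drop_composite",
]

DEFAULT_TREATMENTS = ("unlogged", "simple", "double", "inversion", "mound")

#: Single-letter plot codes used to build composite identifiers (e.g. "N-A").
TREATMENT_CODES = {
    "unlogged": "N",  # natural, unlogged reference
    "simple": "S",
    "double": "D",
    "inversion": "I",
    "mound": "M",
}

#: The ten biogeochemical descriptors used by the multifunctional classifier.
BIOGEOCHEM_VARIABLES = (
    "carbon_pct",
    "sand_pct",
    "silt_pct",
    "clay_pct",
    "nitrogen_pct",
    "ph",
    "h2_uptake",          # nmol g(dw)^-1 h^-1
    "co_uptake",          # nmol g(dw)^-1 h^-1
    "co2_production",     # umol g(dw)^-1 h^-1
    "bacterial_abundance",  # 16S rRNA gene copies g(dw)^-1
)

# Default treatment-level (mean, sd) pairs per variable. These are plausible
# survey-level summaries for loamy-sand boreal podzol microsites in a young
# larch plantation (replicate-level spread); they are defaults of the
# generator, not fitted parameters.
DEFAULT_TREATMENT_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "unlogged": {
        "carbon_pct": (4.9, 1.1), "sand_pct": (83, 3), "silt_pct": (13, 3),
        "clay_pct": (4, 1), "nitrogen_pct": (0.22, 0.04), "ph": (4.3, 0.1),
        "h2_uptake": (6.3, 0.4), "co_uptake": (4.5, 0.6),
        "co2_production": (4.1, 1.3), "bacterial_abundance": (7.9e9, 1.3e9),
    },
    "simple": {
        "carbon_pct": (5.4, 1.3), "sand_pct": (86, 3), "silt_pct": (13, 3),
        "clay_pct": (1, 1), "nitrogen_pct": (0.27, 0.06), "ph": (4.6, 0.2),
        "h2_uptake": (5.8, 1.6), "co_uptake": (4.5, 2.0),
        "co2_production": (3.1, 1.4), "bacterial_abundance": (4.9e9, 3.6e9),
    },
    "double": {
        "carbon_pct": (4.1, 1.2), "sand_pct": (84, 2), "silt_pct": (14, 2),
        "clay_pct": (2, 0), "nitrogen_pct": (0.21, 0.06), "ph": (4.7, 0.2),
        "h2_uptake": (5.2, 1.4), "co_uptake": (3.8, 1.7),
        "co2_production": (1.5, 0.5), "bacterial_abundance": (2.0e9, 2.6e9),
    },
    "inversion": {
        "carbon_pct": (3.0, 1.4), "sand_pct": (76, 2), "silt_pct": (22, 2),
        "clay_pct": (2, 0), "nitrogen_pct": (0.13, 0.04), "ph": (4.7, 0.2),
        "h2_uptake": (3.0, 2.3), "co_uptake": (2.1, 1.4),
        "co2_production": (1.4, 0.2), "bacterial_abundance": (1.5e9, 1.4e9),
    },
    "mound": {
        "carbon_pct": (4.3, 0.8), "sand_pct": (85, 8), "silt_pct": (14, 8),
        "clay_pct": (1, 1), "nitrogen_pct": (0.17, 0.03), "ph": (4.6, 0.2),
        "h2_uptake": (6.6, 4.1), "co_uptake": (4.8, 1.8),
        "co2_production": (1.1, 2.3), "bacterial_abundance": (1.8e9, 2.1e9),
    },
}

#: Physically valid ranges used to truncate the normal draws.
VARIABLE_BOUNDS: dict[str, tuple[float, float]] = {
    "carbon_pct": (0.0, 100.0),
    "sand_pct": (0.0, 100.0),
    "silt_pct": (0.0, 100.0),
    "clay_pct": (0.0, 100.0),
    "nitrogen_pct": (0.0, 100.0),
    "ph": (0.0, 14.0),
    "h2_uptake": (0.0, math.inf),
    "co_uptake": (0.0, math.inf),
    "co2_production": (0.0, math.inf),
    "bacterial_abundance": (0.0, math.inf),
}


class InvalidDesignError(ValueError):
    """Raised when a study design violates its invariants."""


class ConfigurationError(ValueError):
    """Raised when generator parameters are incomplete or inconsistent."""


def child_rng(seed: int, *key: int | str) -> np.random.Generator:
    """Deterministic per-generator child RNG.

    The global ``seed`` seeds a :class:`numpy.random.SeedSequence` whose spawn
    key is the tuple of integers derived from ``key`` (strings are hashed by
    summing code points, keeping the scheme printable and stable across runs).
    """
    ints = tuple(k if isinstance(k, int) else sum(ord(c) for c in k) for k in key)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=ints))


@dataclass(frozen=True)
class StudyDesign:
    """Complete block design: ``n_blocks`` × treatments × replicates per plot."""

    n_blocks: int = 3
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    n_replicates_per_plot: int = 10
    reference_treatment: str = "unlogged"

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_replicates_per_plot < 1:
            raise InvalidDesignError(
                "n_blocks and n_replicates_per_plot must be >= 1, got "
                f"{self.n_blocks} and {self.n_replicates_per_plot}"
            )
        if not self.treatments:
            raise InvalidDesignError("treatments must be non-empty")
        if self.reference_treatment not in self.treatments:
            raise InvalidDesignError(
                f"reference treatment {self.reference_treatment!r} not among "
                f"treatments {self.treatments}"
            )

    @property
    def n_replicate_samples(self) -> int:
        return self.n_blocks * len(self.treatments) * self.n_replicates_per_plot

    @property
    def n_composites(self) -> int:
        return self.n_blocks * len(self.treatments)


def _block_label(i: int) -> str:
    # A, B, ..., Z, AA, AB, ... for arbitrarily many blocks
    label = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def _treatment_code(treatment: str, treatments: tuple[str, ...]) -> str:
    if treatment in TREATMENT_CODES:
        return TREATMENT_CODES[treatment]
    code = treatment[:1].upper() or "T"
    firsts = [t[:1].upper() or "T" for t in treatments]
    if firsts.count(code) > 1:  # disambiguate clashes positionally
        code = f"T{treatments.index(treatment) + 1}"
    return code


def generate_design(design: StudyDesign, seed: int = 0) -> pd.DataFrame:
    """Expand a study design into a replicate-sample metadata table.

    Returns a DataFrame with columns ``sample_id, block, treatment, replicate,
    composite_id``; one row per replicate soil sample, pooled composites
    identified by plot (treatment code + block letter, e.g. ``N-A``). The
    layout is fully determined by the design; ``seed`` is accepted for
    interface symmetry with the stochastic generators.
    """
    del seed
    rows = []
    for b in range(design.n_blocks):
        block = _block_label(b)
        for treatment in design.treatments:
            code = _treatment_code(treatment, design.treatments)
            composite = f"{code}-{block}"
            for r in range(1, design.n_replicates_per_plot + 1):
                rows.append(
                    {
                        "sample_id": f"{composite}-r{r:02d}",
                        "block": block,
                        "treatment": treatment,
                        "replicate": r,
                        "composite_id": composite,
                    }
                )
    return pd.DataFrame(rows)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection-sampled truncated normal; exact, adequate for mild truncation."""
    if sd < 0:
        raise ConfigurationError(f"sd must be >= 0, got {sd}")
    if sd == 0:
        value = min(max(mean, lo), hi)
        return np.full(size, value)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _check_params(
    design: StudyDesign, params: dict[str, dict[str, tuple[float, float]]],
    variables: tuple[str, ...],
) -> None:
    for treatment in design.treatments:
        if treatment not in params:
            raise ConfigurationError(f"missing parameters for treatment {treatment!r}")
        missing = [v for v in variables if v not in params[treatment]]
        if missing:
            raise ConfigurationError(
                f"treatment {treatment!r} missing variables {missing}"
            )


def generate_biogeochem(
    design: StudyDesign,
    params: dict[str, dict[str, tuple[float, float]]] | None = None,
    seed: int = 0,
    *,
    variables: tuple[str, ...] = BIOGEOCHEM_VARIABLES,
    correlation: np.ndarray | None = None,
    return_replicates: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Draw replicate-level biogeochemical profiles and pool them to composites.

    Replicate values are truncated-normal draws (``VARIABLE_BOUNDS``) from each
    treatment's (mean, sd); a composite is the arithmetic mean of its
    replicates, the numerical analogue of physically pooling the soil.
    Variables are drawn independently by default; an optional within-treatment
    ``correlation`` matrix (variables × variables) induces covariance through
    a Cholesky transform, with values clipped to the physical bounds instead
    of rejection-sampled.
    """
    params = DEFAULT_TREATMENT_PARAMS if params is None else params
    _check_params(design, params, variables)
    meta = generate_design(design)
    rng = child_rng(seed, "biogeochem")
    rep = pd.DataFrame(index=meta["sample_id"], columns=list(variables), dtype=float)
    chol = None
    if correlation is not None:
        correlation = np.asarray(correlation, dtype=float)
        if correlation.shape != (len(variables), len(variables)):
            raise ConfigurationError(
                "correlation matrix must be variables x variables"
            )
        chol = np.linalg.cholesky(correlation)
    for treatment in design.treatments:
        mask = (meta["treatment"] == treatment).to_numpy()
        n = int(mask.sum())
        if chol is not None:
            z = rng.standard_normal(size=(n, len(variables))) @ chol.T
            for j, v in enumerate(variables):
                mean, sd = params[treatment][v]
                lo, hi = VARIABLE_BOUNDS.get(v, (-math.inf, math.inf))
                rep.loc[mask, v] = np.clip(mean + sd * z[:, j], lo, hi)
            continue
        for v in variables:
            mean, sd = params[treatment][v]
            lo, hi = VARIABLE_BOUNDS.get(v, (-math.inf, math.inf))
            rep.loc[mask, v] = _truncated_normal(rng, mean, sd, lo, hi, n)
    rep.insert(0, "composite_id", meta["composite_id"].to_numpy())
    composites = rep.groupby("composite_id", sort=False).mean()
    composites.index.name = "composite_id"
    if return_replicates:
        return composites, rep
    return composites


def make_class_offsets(
    class_labels: tuple[str, ...],
    variables: tuple[str, ...],
    offset_sd: float,
    seed: int,
    reference_class: str | None = None,
) -> dict[str, np.ndarray]:
    """Class-centroid offset vectors in per-variable composite-SD units.

    Non-reference classes receive mutually orthogonal random directions (QR of
    a Gaussian matrix), each scaled to norm ``offset_sd * sqrt(p)`` — i.e. a
    per-variable root-mean-square offset of ``offset_sd`` standard deviations.
    Orthogonality guarantees that every *pair* of planted classes is separated
    by at least that magnitude (independently drawn directions can be nearly
    parallel, silently collapsing two classes onto each other). The reference
    class, if given, gets a zero offset so that it sits at the baseline
    centroid.
    """
    rng = child_rng(seed, "class-offsets")
    p = len(variables)
    nonref = [label for label in class_labels if label != reference_class]
    if len(nonref) > p:
        raise ConfigurationError(
            f"cannot plant {len(nonref)} orthogonal class offsets in {p} variables"
        )
    q, _ = np.linalg.qr(rng.normal(size=(p, len(nonref))))
    offsets: dict[str, np.ndarray] = {
        label: q[:, i] * offset_sd * math.sqrt(p) for i, label in enumerate(nonref)
    }
    if reference_class is not None:
        offsets[reference_class] = np.zeros(p)
    return offsets


def generate_classed_biogeochem(
    design: StudyDesign,
    class_assignment: dict[str, str],
    seed: int = 0,
    *,
    params: dict[str, dict[str, tuple[float, float]]] | None = None,
    variables: tuple[str, ...] = BIOGEOCHEM_VARIABLES,
    offset_sd: float = 3.0,
    reference_class: str | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Composite profiles with a planted class structure of known ground truth.

    All replicates are drawn from the reference treatment's parameters, then
    each composite's class offset (see :func:`make_class_offsets`) is added,
    scaled by that variable's composite-level SD (replicate SD / sqrt(n_reps)
    — the spread the downstream classifier actually sees). Returns the
    composite table and the planted composite → class map.
    """
    params = DEFAULT_TREATMENT_PARAMS if params is None else params
    base = params[design.reference_treatment]
    flat = {t: base for t in design.treatments}
    composites = generate_biogeochem(
        design, flat, seed=seed, variables=variables
    )
    missing = [c for c in composites.index if c not in class_assignment]
    if missing:
        raise ConfigurationError(f"composites without a class assignment: {missing}")
    labels = tuple(dict.fromkeys(class_assignment[c] for c in composites.index))
    offsets = make_class_offsets(
        labels, variables, offset_sd, seed, reference_class=reference_class
    )
    comp_sd = np.array(
        [base[v][1] / math.sqrt(design.n_replicates_per_plot) for v in variables]
    )
    for comp in composites.index:
        composites.loc[comp] += offsets[class_assignment[comp]] * comp_sd
    # re-clip to physical bounds after shifting
    for v in variables:
        lo, hi = VARIABLE_BOUNDS.get(v, (-math.inf, math.inf))
        composites[v] = composites[v].clip(lo, hi)
    truth = {c: class_assignment[c] for c in composites.index}
    return composites, truth


def generate_gas_timeseries(
    true_k: float,
    c0: float,
    c_floor: float,
    times: np.ndarray,
    noise_sd: float,
    seed: int = 0,
    *,
    mode: str = "uptake",
    slope: float = 0.0,
) -> pd.DataFrame:
    """Headspace mole-fraction series for one microcosm assay.

    Uptake mode follows first-order decay toward the compensation point,
    chi(t) = c_floor + (c0 - c_floor) exp(-k t); production mode is linear,
    chi(t) = c0 + slope * t. Gaussian measurement noise of SD ``noise_sd``
    (ppmv) is added to every point. Returns columns ``time_h, ppmv``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D array")
    if mode == "uptake":
        if true_k < 0:
            raise ValueError("true_k must be >= 0")
        if not c0 > c_floor or c_floor < 0:
            raise ValueError("require c0 > c_floor >= 0")
        clean = c_floor + (c0 - c_floor) * np.exp(-true_k * times)
    elif mode == "production":
        clean = c0 + slope * times
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rng = child_rng(seed, "gas")
    noisy = clean + rng.normal(0.0, noise_sd, size=times.size) if noise_sd > 0 else clean
    return pd.DataFrame({"time_h": times, "ppmv": noisy})


@dataclass(frozen=True)
class PlantedCommunity:
    """Shared log-normal community plus class-restricted rare indicators.

    ``indicator_spec`` maps class label → list of planted indicator OTU ids;
    each planted indicator is given relative abundance ``indicator_fraction``
    (< 0.001, the rare biosphere) in samples of its class and exactly zero
    elsewhere.
    """

    n_otus: int = 200
    base_log_abundance_params: tuple[float, float] = (0.0, 1.5)
    indicator_spec: dict[str, tuple[str, ...]] = field(default_factory=dict)
    indicator_fraction: float = 5e-4
    library_size_range: tuple[int, int] = (166_040, 166_040)

    def __post_init__(self) -> None:
        if not 0 < self.indicator_fraction < 1e-3:
            raise ConfigurationError(
                "planted indicator relative abundance must lie in (0, 0.001) "
                f"(rare biosphere), got {self.indicator_fraction}"
            )
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"invalid library_size_range {self.library_size_range}")


def generate_otu_table(
    design: StudyDesign,
    community: PlantedCommunity,
    class_assignment: dict[str, str],
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Multinomial OTU counts per composite with planted class indicators.

    Returns ``(counts, ground_truth)``: counts is a composites × OTUs integer
    DataFrame (shared OTUs ``otu0001``... plus one column per planted
    indicator); ground_truth records planted indicator → class and the drawn
    library sizes.
    """
    meta = generate_design(design)
    composites = list(dict.fromkeys(meta["composite_id"]))
    missing = [c for c in composites if c not in class_assignment]
    if missing:
        raise ConfigurationError(f"composites without a class assignment: {missing}")
    rng = child_rng(seed, "otu")
    loc, scale = community.base_log_abundance_params
    shared = rng.lognormal(loc, scale, size=community.n_otus)
    shared /= shared.sum()
    shared_ids = [f"otu{i + 1:04d}" for i in range(community.n_otus)]
    indicator_ids = [o for otus in community.indicator_spec.values() for o in otus]
    if len(set(indicator_ids)) != len(indicator_ids):
        raise ConfigurationError("indicator OTU ids must be unique across classes")
    otu_ids = shared_ids + indicator_ids
    indicator_class = {
        otu: cls for cls, otus in community.indicator_spec.items() for otu in otus
    }
    lo, hi = community.library_size_range
    counts = np.zeros((len(composites), len(otu_ids)), dtype=np.int64)
    lib_sizes = {}
    for i, comp in enumerate(composites):
        cls = class_assignment[comp]
        probs = np.zeros(len(otu_ids))
        planted = [j for j, otu in enumerate(indicator_ids) if indicator_class[otu] == cls]
        planted_mass = community.indicator_fraction * len(planted)
        probs[: community.n_otus] = shared * (1.0 - planted_mass)
        for j in planted:
            probs[community.n_otus + j] = community.indicator_fraction
        lib = int(rng.integers(lo, hi + 1))
        lib_sizes[comp] = lib
        counts[i] = rng.multinomial(lib, probs)
    table = pd.DataFrame(counts, index=pd.Index(composites, name="composite_id"),
                         columns=otu_ids)
    truth = {
        "indicator_class": indicator_class,
        "library_sizes": lib_sizes,
        "indicator_fraction": community.indicator_fraction,
    }
    return table, truth


def drop_composite(
    counts: pd.DataFrame,
    biogeochem: pd.DataFrame,
    composite: str,
    abundance_floor: float,
    abundance_variable: str = "bacterial_abundance",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulate a failed DNA extraction for one composite.

    Drops the composite's OTU library and substitutes ``abundance_floor``
    (e.g. a qPCR detection limit) for its bacterial abundance, leaving every
    other measurement untouched.
    """
    if composite not in counts.index:
        raise KeyError(f"composite {composite!r} not in OTU table")
    out_counts = counts.drop(index=composite)
    out_bio = biogeochem.copy()
    out_bio.loc[composite, abundance_variable] = abundance_floor
    return out_counts, out_bio
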