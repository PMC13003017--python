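"""Synthetic datasets with the exact generative structure the models assume.

Every generator is a pure function of (design, truth overrides, seed) and
returns a ground-truth record alongside the data, so parameter-recovery
tests can close the simulate -> fit -> recover loop without any external
downloads.

The default design emulates the study conditions: a 1908-2021 span, five
aging methods dominated by otolith readings, three latitude bands, three
management classes, a sampling-intensity curve that rises from the 1950s,
peaks in the early 2000s and declines after 2010, and a sea-surface
temperature field warming by roughly 1 degree C across the series.  The
default scale is about a tenth of the real compilation (~150 species, ~800
observations) so recovery suites run in minutes; the full scale (~7700
observations, ~1500 species) is a parameter, not a different code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .covariates import MANAGEMENT_CLASSES, SSTGrid
from .growth_metrics import AGING_METHODS, ValidationError
from .trend_model import StateSpaceData
from .phylo_model import tree_to_correlation


# ---------------------------------------------------------------------------
# Designs and truth records
# ---------------------------------------------------------------------------


@dataclass
class SimulationDesign:
    """Sampling frame for the generators.

    ``method_mix`` and ``management_mix`` are proportions summing to one;
    the per-year sampling-intensity curve is a discretised triangular ramp
    from ``ramp_start`` to a peak at ``ramp_peak`` falling off after
    ``ramp_decline`` (the exact shape is cosmetic).
    """

    n_obs: int = 800
    n_species: int = 150
    n_families: int = 12
    year_start: int = 1908
    year_end: int = 2021
    method_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "otolith": 0.55,
            "length_frequency": 0.20,
            "other_rings": 0.12,
            "mark_recapture": 0.08,
            "unknown": 0.05,
        }
    )
    management_mix: Mapping[str, float] = field(
        default_factory=lambda: {"managed": 0.55, "unmanaged": 0.30, "unfished": 0.15}
    )
    ramp_start: int = 1950
    ramp_peak: int = 2005
    ramp_decline: int = 2010
    base_intensity: float = 0.25
    # SST grid frame
    grid_lat_step: float = 1.0
    grid_lon_step: float = 1.0
    grid_lat_range: tuple[float, float] = (-69.5, 69.5)
    grid_lon_range: tuple[float, float] = (-179.5, 179.5)
    sst_trend_per_span: float = 1.0
    sst_noise_sd: float = 0.3
    land_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.year_end < self.year_start:
            raise ValidationError("empty year span")
        for name, mix in (("method_mix", self.method_mix), ("management_mix", self.management_mix)):
            total = sum(mix.values())
            if not math.isclose(total, 1.0, rel_tol=1e-6):
                raise ValidationError(f"{name} proportions sum to {total}, not 1")
        unknown_methods = set(self.method_mix) - set(AGING_METHODS)
        if unknown_methods:
            raise ValidationError(f"unknown methods in mix: {sorted(unknown_methods)}")
        unknown_classes = set(self.management_mix) - set(MANAGEMENT_CLASSES)
        if unknown_classes:
            raise ValidationError(f"unknown classes in mix: {sorted(unknown_classes)}")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    def year_weights(self) -> np.ndarray:
        """Discretised triangular sampling-intensity ramp, normalised to sum 1."""
        w = np.full(self.n_years, self.base_intensity)
        years = self.years
        rise = (years >= self.ramp_start) & (years <= self.ramp_peak)
        w[rise] += (years[rise] - self.ramp_start) / max(self.ramp_peak - self.ramp_start, 1)
        fall = years > self.ramp_decline
        w[fall] = self.base_intensity + np.maximum(
            0.0, 1.0 - (years[fall] - self.ramp_decline) / 10.0
        )
        return w / w.sum()


@dataclass
class SyntheticTruth:
    """Ground-truth generative parameters emitted with every simulated dataset."""

    seed: int
    u: float | None = None
    sigma_q: float | None = None
    sigma_r: dict[str, float] | None = None
    scalars: dict[str, float] | None = None
    tau: float | None = None
    beta: float | None = None
    x0: float | None = None
    x_path: np.ndarray | None = None
    family_effects: np.ndarray | None = None
    sigma_fam: float | None = None
    # PGLMM side
    beta0: float | None = None
    class_slopes: dict[str, float] | None = None
    class_offsets: dict[str, float] | None = None
    sigma_species: float | None = None
    sigma_method: float | None = None
    sigma_year: float | None = None
    sigma_phylo: float | None = None
    species_effects: np.ndarray | None = None
    phylo_effects: np.ndarray | None = None
    newick: str | None = None

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if v is None:
                continue
            if isinstance(v, np.ndarray):
                out[k] = v.tolist()
            else:
                out[k] = v
        return out


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def simulate_tree(n_tips: int, seed: int = 0) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree with depth normalised to 1.

    Tips are labelled ``sp0001``... in namespace order.  Implemented by the
    standard forward construction: starting from two lineages, waiting times
    between speciation events are exponential in the number of extant
    lineages, and the lineage that splits is chosen uniformly.
    """
    if n_tips < 2:
        raise ValidationError("a tree needs at least 2 tips")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))

    # event times: birth rate 1, k lineages wait Exp(k)
    times = [0.0]
    t = 0.0
    for k in range(2, n_tips):
        t += rng.exponential(1.0 / k)
        times.append(t)
    total_depth = t + rng.exponential(1.0 / n_tips)

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = True
    root = tree.seed_node
    root.birth_time = 0.0

    # active list of leaf nodes awaiting either a split or the present day
    a = root.new_child()
    b = root.new_child()
    a.birth_time = b.birth_time = 0.0
    active = [a, b]
    for split_time in times[1:]:
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.edge.length = split_time - node.birth_time
        left = node.new_child()
        right = node.new_child()
        left.birth_time = right.birth_time = split_time
        active.extend([left, right])

    for i, node in enumerate(active):
        node.edge.length = total_depth - node.birth_time

    # normalise depth to 1 and label tips deterministically
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= total_depth
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxon_namespace.new_taxon(label=f"sp{i + 1:04d}")
    return tree


def count_cherries(tree: dendropy.Tree) -> int:
    """Internal nodes whose two children are both leaves."""
    n = 0
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if len(children) == 2 and all(c.is_leaf() for c in children):
            n += 1
    return n


# ---------------------------------------------------------------------------
# Shared taxonomic/spatial frame
# ---------------------------------------------------------------------------


def _species_frame(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Species -> family, management class, latitude/longitude home location."""
    n = design.n_species
    families = [f"fam{i + 1:03d}" for i in range(design.n_families)]
    fam_of_species = rng.integers(design.n_families, size=n)

    classes = list(design.management_mix)
    probs = np.array([design.management_mix[c] for c in classes])
    fam_class = rng.choice(len(classes), size=design.n_families, p=probs)

    lat = rng.uniform(-60.0, 65.0, size=n)
    lon = rng.uniform(-179.0, 179.0, size=n)
    return pd.DataFrame(
        {
            "species": [f"sp{i + 1:04d}" for i in range(n)],
            "family": [families[f] for f in fam_of_species],
            "family_index": fam_of_species,
            "management": [classes[fam_class[f]] for f in fam_of_species],
            "latitude": lat,
            "longitude": lon,
        }
    )


def _latitudinal_mean_sst(lat: np.ndarray) -> np.ndarray:
    """Smooth poleward-cooling profile: ~28 C at the equator, ~2 C at 65 deg."""
    return 28.0 - 26.0 * (np.abs(lat) / 65.0) ** 1.6


# ---------------------------------------------------------------------------
# State-space dataset
# ---------------------------------------------------------------------------

_TREND_DEFAULTS = dict(
    # drift implied by a 7.9% decline of the response over 113 annual steps
    u=-0.00073,
    sigma_q=0.004,
    sigma_r={
        "otolith": 0.02,
        "mark_recapture": 0.04,
        "other_rings": 0.03,
        "length_frequency": 0.03,
        "unknown": 0.05,
    },
    scalars={"mark_recapture": 0.05, "other_rings": -0.03,
             "length_frequency": 0.02, "unknown": 0.0},
    tau=200.0,
    beta=0.02,
    x0=math.log(3.3),
    sigma_fam=0.08,
)


def simulate_trend_dataset(
    design: SimulationDesign | None = None,
    truth: Mapping[str, object] | None = None,
    seed: int = 0,
) -> tuple[StateSpaceData, pd.DataFrame, SyntheticTruth]:
    """Forward-simulate the state-space model.

    Draws the latent walk x_t with drift and process noise, adds family
    effects, method scalars and per-method annual deviations, applies the
    log link with the temperature term, and draws gamma observations with
    shape tau.  Returns the model-ready container, the observation table
    (with species/family/location columns for downstream stages), and the
    truth record.
    """
    design = design or SimulationDesign()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    params = dict(_TREND_DEFAULTS)
    if truth:
        params.update(truth)

    T = design.n_years
    methods = list(design.method_mix)
    sigma_r = {m: params["sigma_r"][m] for m in methods}
    scalars = {m: params["scalars"].get(m, 0.0) for m in methods if m != "otolith"}

    w = rng.normal(0.0, params["sigma_q"], size=T)
    x = params["x0"] + params["u"] * np.arange(1, T + 1) + np.cumsum(w)

    frame = _species_frame(design, rng)
    fam_effects = rng.normal(0.0, params["sigma_fam"], size=design.n_families)

    sp_idx = rng.integers(design.n_species, size=design.n_obs)
    year_idx = rng.choice(T, size=design.n_obs, p=design.year_weights())
    method_idx = rng.choice(
        len(methods), size=design.n_obs,
        p=np.array([design.method_mix[m] for m in methods]),
    )

    # per-(method, year) observation deviations
    v = np.column_stack([rng.normal(0.0, sigma_r[m], size=T) for m in methods])

    lat = frame["latitude"].to_numpy()[sp_idx]
    span = max(design.n_years - 1, 1)
    sst = (
        _latitudinal_mean_sst(lat)
        + design.sst_trend_per_span * year_idx / span
        + rng.normal(0.0, design.sst_noise_sd, size=design.n_obs)
    )
    x_centred = sst - sst.mean()

    c_arr = np.array([0.0 if m == "otolith" else scalars[m] for m in methods])
    fam_idx = frame["family_index"].to_numpy()[sp_idx]
    log_mu = (
        x[year_idx]
        + c_arr[method_idx]
        + v[year_idx, method_idx]
        + fam_effects[fam_idx]
        + params["beta"] * x_centred
    )
    tau = params["tau"]
    y = rng.gamma(shape=tau, scale=np.exp(log_mu) / tau)

    table = pd.DataFrame(
        {
            "phi": y,
            "year": design.years[year_idx],
            "species": frame["species"].to_numpy()[sp_idx],
            "family": frame["family"].to_numpy()[sp_idx],
            "management": frame["management"].to_numpy()[sp_idx],
            "aging_method": [methods[i] for i in method_idx],
            "latitude": lat,
            "longitude": frame["longitude"].to_numpy()[sp_idx],
            "sst": sst,
        }
    )

    methods_order = [m for m in AGING_METHODS if m in set(table["aging_method"])]
    m_map = {m: i for i, m in enumerate(methods_order)}
    fam_labels = sorted(set(table["family"]))
    f_map = {f: i for i, f in enumerate(fam_labels)}
    data = StateSpaceData(
        y=y,
        year_index=year_idx,
        family_index=np.array([f_map[f] for f in table["family"]]),
        method_index=np.array([m_map[m] for m in table["aging_method"]]),
        x_sst=x_centred,
        years=design.years,
        methods=tuple(methods_order),
        n_families=len(fam_labels),
    )
    truth_rec = SyntheticTruth(
        seed=seed,
        u=params["u"],
        sigma_q=params["sigma_q"],
        sigma_r=sigma_r,
        scalars=scalars,
        tau=tau,
        beta=params["beta"],
        x0=params["x0"],
        x_path=x,
        family_effects=fam_effects,
        sigma_fam=params["sigma_fam"],
    )
    return data, table, truth_rec


# ---------------------------------------------------------------------------
# PGLMM dataset
# ---------------------------------------------------------------------------

_PGLMM_DEFAULTS = dict(
    beta0=math.log(3.2),
    # per-class temperature slopes on the log-mean scale (per deg C)
    class_slopes={"managed": -0.00011, "unmanaged": 0.023, "unfished": 0.040},
    class_offsets={"managed": 0.05, "unmanaged": -0.05, "unfished": 0.0},
    tau=200.0,
    sigma_species=0.08,
    sigma_method=0.03,
    sigma_year=0.02,
    sigma_phylo=0.08,
)


def simulate_pglmm_dataset(
    design: SimulationDesign | None = None,
    truth: Mapping[str, object] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dendropy.Tree, SyntheticTruth]:
    """Forward-simulate the phylogenetic gamma GLMM.

    Species intercepts are iid normal; phylogenetic effects are multivariate
    normal with covariance sigma_phylo^2 times the Brownian correlation of a
    simulated Yule tree; per-class temperature slopes and offsets apply on
    the log-mean scale; observations are gamma with shape tau.
    """
    design = design or SimulationDesign()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    params = dict(_PGLMM_DEFAULTS)
    if truth:
        params.update(truth)

    tree = simulate_tree(design.n_species, seed=seed + 1)
    species = [f"sp{i + 1:04d}" for i in range(design.n_species)]
    corr = tree_to_correlation(tree, species)

    frame = _species_frame(design, rng)
    sp_effects = rng.normal(0.0, params["sigma_species"], size=design.n_species)
    L = corr.cholesky()
    phylo_effects = params["sigma_phylo"] * (L @ rng.standard_normal(design.n_species))

    methods = list(design.method_mix)
    meth_effects = rng.normal(0.0, params["sigma_method"], size=len(methods))
    yr_effects = rng.normal(0.0, params["sigma_year"], size=design.n_years)

    sp_idx = rng.integers(design.n_species, size=design.n_obs)
    year_idx = rng.choice(design.n_years, size=design.n_obs, p=design.year_weights())
    method_idx = rng.choice(
        len(methods), size=design.n_obs,
        p=np.array([design.method_mix[m] for m in methods]),
    )

    lat = frame["latitude"].to_numpy()[sp_idx]
    span = max(design.n_years - 1, 1)
    sst = (
        _latitudinal_mean_sst(lat)
        + design.sst_trend_per_span * year_idx / span
        + rng.normal(0.0, design.sst_noise_sd, size=design.n_obs)
    )
    x_centred = sst - sst.mean()

    mgmt = frame["management"].to_numpy()[sp_idx]
    slopes = np.array([params["class_slopes"][c] for c in mgmt])
    offsets = np.array([params["class_offsets"][c] for c in mgmt])

    log_mu = (
        params["beta0"]
        + offsets
        + slopes * x_centred
        + sp_effects[sp_idx]
        + phylo_effects[sp_idx]
        + meth_effects[method_idx]
        + yr_effects[year_idx]
    )
    tau = params["tau"]
    y = rng.gamma(shape=tau, scale=np.exp(log_mu) / tau)

    table = pd.DataFrame(
        {
            "phi": y,
            "species": frame["species"].to_numpy()[sp_idx],
            "family": frame["family"].to_numpy()[sp_idx],
            "management": mgmt,
            "aging_method": [methods[i] for i in method_idx],
            "year": design.years[year_idx],
            "latitude": lat,
            "longitude": frame["longitude"].to_numpy()[sp_idx],
            "sst": sst,
        }
    )
    truth_rec = SyntheticTruth(
        seed=seed,
        beta0=params["beta0"],
        class_slopes=dict(params["class_slopes"]),
        class_offsets=dict(params["class_offsets"]),
        tau=tau,
        sigma_species=params["sigma_species"],
        sigma_method=params["sigma_method"],
        sigma_year=params["sigma_year"],
        sigma_phylo=params["sigma_phylo"],
        species_effects=sp_effects,
        phylo_effects=phylo_effects,
        newick=tree.as_string(schema="newick"),
    )
    return table, tree, truth_rec


# ---------------------------------------------------------------------------
# SST grid
# ---------------------------------------------------------------------------


def simulate_sst_grid(
    design: SimulationDesign | None = None, seed: int = 0
) -> SSTGrid:
    """Latitudinal temperature gradient + linear secular trend + noise.

    The default trend adds 1 degree C across the full span, matching the
    roughly one-degree warming the study period saw; an optional random
    land mask drops a fraction of cells to NaN.
    """
    design = design or SimulationDesign()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    lats = np.arange(design.grid_lat_range[0], design.grid_lat_range[1] + 1e-9,
                     design.grid_lat_step)
    lons = np.arange(design.grid_lon_range[0], design.grid_lon_range[1] + 1e-9,
                     design.grid_lon_step)
    years = design.years
    span = max(len(years) - 1, 1)
    base = _latitudinal_mean_sst(lats)[None, :, None]
    trend = (design.sst_trend_per_span * np.arange(len(years)) / span)[:, None, None]
    noise = (
        rng.normal(0.0, design.sst_noise_sd, size=(len(years), len(lats), len(lons)))
        if design.sst_noise_sd > 0
        else 0.0
    )
    values = base + trend + noise
    values = np.broadcast_to(values, (len(years), len(lats), len(lons))).copy()
    if design.land_fraction > 0:
        mask = rng.uniform(size=(len(lats), len(lons))) < design.land_fraction
        values[:, mask] = np.nan
    return SSTGrid(years=years, lats=lats, lons=lons, values=values)
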