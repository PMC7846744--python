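"""Synthetic climate worlds and virtual species with known niches.

This module generates everything the pipeline needs to run — and be
validated — without external data: monthly climate cubes for an observed
baseline, a (biased) model baseline and five scenario trajectories; a realm
mask; and virtual species whose true Gaussian niche envelopes are known, so
downstream range-change estimates can be compared with an exact oracle.

The scenario set mirrors a freshwater-hosing experiment design: a
high-warming control trajectory (``RCP85``) plus four hosing scenarios
``A``–``D`` that superimpose 0.11, 0.22, 0.34 and 0.68 Sv of North-Atlantic
freshwater forcing over 2020–2070.  In the synthetic world the hosing
response is a regional cooling and drying that ramps linearly over the
forcing window and persists afterwards (AMOC weakening does not recover on
the century scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .climate_prep import BIOCLIM_VARS, BioclimStack, compute_bioclim, horizon_mean
from .cube import ClimateCube
from .errors import ConfigurationError, GenerationError, RangeUndefinedError
from .grid import GridSpec, RealmMask, make_realm_mask, realm_names_for
from .seeds import derived_seed

HOSING_FORCINGS_SV = {"RCP85": 0.0, "A": 0.11, "B": 0.22, "C": 0.34, "D": 0.68}
ALLOWED_FORCINGS = (0.0, 0.11, 0.22, 0.34, 0.68)

#: Default hosing response amplitudes per Sv of forcing.  The drying is the
#: ecologically dominant response, consistent with the large precipitation
#: reductions hosing experiments project for the affected region; the
#: regional cooling is kept small relative to the warming trend so that a
#: hosing scenario always adds net climate stress over the control rather
#: than partially cancelling it.
COOLING_PER_SV = 1.0  # °C at full ramp
PRECIP_ANOMALY_PER_SV = -0.9  # fraction at full ramp

IUCN_STATUSES = ("LC", "NT", "VU", "EN", "CR", "DD")
_STATUS_WEIGHTS = (0.45, 0.12, 0.16, 0.14, 0.08, 0.05)


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario trajectory: secular warming plus optional hosing anomaly."""

    label: str
    forcing_sv: float
    warming_rate: float = 0.4  # °C per decade beyond the baseline end
    forcing_window: tuple[int, int] = (2020, 2070)
    hosing_cooling_amplitude: float = 0.0  # °C at full ramp, >= 0
    hosing_region: tuple[str, ...] = ()
    precip_anomaly: float = 0.0  # fractional change at full ramp

    def __post_init__(self) -> None:
        if not any(abs(self.forcing_sv - f) < 1e-12 for f in ALLOWED_FORCINGS):
            raise ConfigurationError(
                f"forcing_sv must be one of {ALLOWED_FORCINGS}, got {self.forcing_sv}"
            )
        if self.forcing_sv == 0.0 and (
            self.hosing_cooling_amplitude != 0.0 or self.precip_anomaly != 0.0
        ):
            raise ConfigurationError("hosing terms must be zero when forcing_sv = 0")

    def ramp(self, year: np.ndarray | int) -> np.ndarray:
        """Hosing ramp: 0 before the window, linear within, 1 after."""
        w0, w1 = self.forcing_window
        return np.clip((np.asarray(year, dtype=float) - w0) / (w1 - w0), 0.0, 1.0)


def default_scenarios(
    hosing_region: tuple[str, ...] = ("Afrotropical",),
    warming_rate: float = 0.4,
) -> tuple[ScenarioSpec, ...]:
    """Control + four hosing scenarios with amplitudes scaled by forcing."""
    specs = [ScenarioSpec(label="RCP85", forcing_sv=0.0, warming_rate=warming_rate)]
    for label in ("A", "B", "C", "D"):
        sv = HOSING_FORCINGS_SV[label]
        specs.append(
            ScenarioSpec(
                label=label,
                forcing_sv=sv,
                warming_rate=warming_rate,
                hosing_cooling_amplitude=COOLING_PER_SV * sv,
                hosing_region=hosing_region,
                precip_anomaly=PRECIP_ANOMALY_PER_SV * sv,
            )
        )
    return tuple(specs)


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of one synthetic world."""

    grid_shape: tuple[int, int] = (42, 81)
    cell_size: float = 0.33
    n_realms: int = 2
    baseline_years: tuple[int, int] = (1970, 2000)  # inclusive
    scenario_years: tuple[int, int] = (2006, 2100)  # inclusive
    horizons: tuple[int, ...] = (2030, 2050, 2070)
    scenario_specs: tuple[ScenarioSpec, ...] | None = None
    noise_sd: float = 0.4  # °C, interannual additive temperature noise
    prec_noise_sigma: float = 0.08  # log-sd of multiplicative precipitation noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ConfigurationError("grid_shape must be positive")
        if self.n_realms < 1:
            raise ConfigurationError("n_realms must be >= 1")
        if self.baseline_years[0] > self.baseline_years[1]:
            raise ConfigurationError("baseline_years must be an increasing range")
        for h in self.horizons:
            if not (self.scenario_years[0] <= h <= self.scenario_years[1]):
                raise ConfigurationError(f"horizon {h} outside scenario years")
        if self.scenario_specs is None:
            region = (realm_names_for(self.n_realms)[0],)
            object.__setattr__(self, "scenario_specs", default_scenarios(region))

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_shape[0], self.grid_shape[1], self.cell_size)


@dataclass
class WorldRealization:
    """Output bundle of :func:`generate_climate_world`."""

    spec: WorldSpec
    realm_mask: RealmMask
    obs_baseline: ClimateCube
    model_baseline: ClimateCube
    scenarios: dict[str, ClimateCube]
    injected_bias: dict[str, np.ndarray]  # var -> (12, rows, cols) model - obs offset

    def baseline_bioclim(self) -> BioclimStack:
        """Bioclim stack of the observed baseline climatology (current climate)."""
        y0, y1 = self.spec.baseline_years
        center = (y0 + y1 + 1) // 2
        clim = horizon_mean(self.obs_baseline, center_year=center, width=y1 - y0 + 1)
        stack = compute_bioclim(clim)
        stack.label = "observed baseline"
        return stack


def _climatological_means(grid: GridSpec) -> dict[str, np.ndarray]:
    """Smooth mean monthly fields with latitudinal and seasonal structure.

    Returns (12, rows, cols) arrays for tmean plus the non-negative
    half-widths that place tmin/tmax around it, and precipitation.
    """
    months = np.arange(12)
    lat = np.linspace(0.0, 1.0, grid.n_rows)[:, None]  # 0 = north edge
    lon = np.linspace(0.0, 1.0, grid.n_cols)[None, :]
    season = np.cos(2 * np.pi * (months[:, None, None] - 6) / 12.0)

    # warm south, cool north; stronger seasonal cycle toward the north
    tmean = (2.0 + 20.0 * lat + 2.0 * np.sin(2 * np.pi * lon))[None] - (
        (3.0 + 7.0 * (1 - lat))[None] * season
    )
    dtr_half = np.maximum(
        (3.5 + 1.5 * (1 - lat))[None] - 0.8 * season * (1 - lat)[None], 0.5
    )  # (12, rows, 1), broadcastable over columns

    # wetter toward the south-east, with longitude-phased seasonality so
    # precipitation seasonality (bio15) varies spatially
    prec_base = 40.0 + 70.0 * lat + 40.0 * (0.5 + 0.5 * np.sin(2 * np.pi * lon))
    prec_season = 1.0 + (0.25 + 0.35 * lon) * np.cos(
        2 * np.pi * (months[:, None, None] - 1) / 12.0 + np.pi * lat
    )
    prec = np.maximum(prec_base[None] * prec_season, 1.0)
    return {"tmean": tmean, "dtr_half": dtr_half, "prec": prec}


def _bias_fields(grid: GridSpec) -> dict[str, np.ndarray]:
    """Fixed smooth model-minus-observed bias patterns (12, rows, cols)."""
    lat = np.linspace(0.0, 1.0, grid.n_rows)[:, None]
    lon = np.linspace(0.0, 1.0, grid.n_cols)[None, :]
    months = np.arange(12)[:, None, None]
    t_bias = (0.8 + 1.2 * np.sin(2 * np.pi * lon) * np.cos(np.pi * lat))[None] + (
        0.3 * np.cos(2 * np.pi * months / 12.0)
    )
    p_bias = (8.0 * np.cos(np.pi * lat) - 4.0 * np.sin(2 * np.pi * lon))[None] * np.ones(
        (12, 1, 1)
    )
    return {"t": t_bias * np.ones((12, grid.n_rows, grid.n_cols)), "prec": p_bias}


def _realize_cube(
    grid: GridSpec,
    years: np.ndarray,
    means: dict[str, np.ndarray],
    rng: np.random.Generator,
    *,
    noise_sd: float,
    prec_noise_sigma: float,
    t_offset: np.ndarray | None = None,  # (n_years, 12, rows, cols) or None
    prec_factor: np.ndarray | None = None,
    t_bias: np.ndarray | None = None,
    p_bias: np.ndarray | None = None,
    label: str = "",
) -> ClimateCube:
    ny = len(years)
    shape = (ny, 12, grid.n_rows, grid.n_cols)
    tmean = np.broadcast_to(means["tmean"], shape).copy()
    dtr = np.broadcast_to(means["dtr_half"], shape)
    prec = np.broadcast_to(means["prec"], shape).copy()

    if t_bias is not None:
        tmean += t_bias
    if t_offset is not None:
        tmean += t_offset
    tmean += rng.normal(0.0, noise_sd, size=shape)

    # widen the diurnal envelope with independent non-negative jitter so the
    # ordering tmin <= tmean <= tmax holds pointwise by construction
    up = dtr + np.abs(rng.normal(0.0, 0.3, size=shape))
    dn = dtr + np.abs(rng.normal(0.0, 0.3, size=shape))

    if p_bias is not None:
        prec = prec + p_bias
    if prec_factor is not None:
        prec = prec * prec_factor
    lognoise = rng.normal(0.0, prec_noise_sigma, size=shape)
    prec = prec * np.exp(lognoise - 0.5 * prec_noise_sigma**2)
    prec = np.maximum(prec, 0.0)

    return ClimateCube(
        grid=grid,
        years=years,
        data={"tmean": tmean, "tmax": tmean + up, "tmin": tmean - dn, "prec": prec},
        label=label,
    )


def generate_climate_world(spec: WorldSpec) -> WorldRealization:
    """Generate observed/model baselines, scenario cubes and the realm mask.

    Deterministic given ``spec.seed``.  The observed baseline is stationary
    in expectation; the model baseline carries a fixed injected bias field;
    scenario cubes add the warming trend from the baseline end and, for
    hosing scenarios, the regional cooling/drying anomaly within the
    forcing window (persisting after it).
    """
    grid = spec.grid
    realm_mask = make_realm_mask(grid, spec.n_realms)
    means = _climatological_means(grid)
    bias = _bias_fields(grid)

    y0, y1 = spec.baseline_years
    base_years = np.arange(y0, y1 + 1)
    s0, s1 = spec.scenario_years
    scen_years = np.arange(s0, s1 + 1)

    obs = _realize_cube(
        grid,
        base_years,
        means,
        np.random.default_rng(derived_seed(spec.seed, "obs_baseline")),
        noise_sd=spec.noise_sd,
        prec_noise_sigma=spec.prec_noise_sigma,
        label="observed baseline",
    )
    model_base = _realize_cube(
        grid,
        base_years,
        means,
        np.random.default_rng(derived_seed(spec.seed, "model_baseline")),
        noise_sd=spec.noise_sd,
        prec_noise_sigma=spec.prec_noise_sigma,
        t_bias=bias["t"][None],
        p_bias=bias["prec"][None],
        label="model baseline",
    )

    scenarios: dict[str, ClimateCube] = {}
    for scen in spec.scenario_specs:
        for realm in scen.hosing_region:
            if realm not in realm_mask.names:
                raise ConfigurationError(
                    f"hosing_region names unknown realm {realm!r}; "
                    f"known realms: {realm_mask.names}"
                )
        warming = scen.warming_rate * (scen_years - y1) / 10.0  # °C, per year
        t_offset = warming[:, None, None, None] * np.ones(
            (1, 12, grid.n_rows, grid.n_cols)
        )
        prec_factor = np.ones_like(t_offset)
        if scen.forcing_sv > 0 and scen.hosing_region:
            region = np.zeros(grid.shape, dtype=bool)
            for realm in scen.hosing_region:
                region |= realm_mask.mask_for(realm)
            ramp = scen.ramp(scen_years)[:, None, None, None]
            t_offset -= scen.hosing_cooling_amplitude * ramp * region[None, None]
            prec_factor += scen.precip_anomaly * ramp * region[None, None]
        cube = _realize_cube(
            grid,
            scen_years,
            means,
            np.random.default_rng(derived_seed(spec.seed, "scenario", scen.label)),
            noise_sd=spec.noise_sd,
            prec_noise_sigma=spec.prec_noise_sigma,
            t_bias=bias["t"][None],
            p_bias=bias["prec"][None],
            t_offset=t_offset,
            prec_factor=np.maximum(prec_factor, 0.0),
            label=f"scenario {scen.label}",
        )
        scenarios[scen.label] = cube

    return WorldRealization(
        spec=spec,
        realm_mask=realm_mask,
        obs_baseline=obs,
        model_baseline=model_base,
        scenarios=scenarios,
        injected_bias={"tmean": bias["t"], "tmax": bias["t"], "tmin": bias["t"], "prec": bias["prec"]},
    )


# ---------------------------------------------------------------------------
# virtual species


@dataclass(frozen=True)
class NicheSpec:
    """How virtual niches are drawn around realm climates.

    ``breadth_range`` scales niche widths as multiples of the realm-wide
    standard deviation of each bioclim variable; ``threshold_range`` bounds
    the suitability cutoff s* defining the realized range; ``optimum_jitter``
    displaces the optimum from the anchor cell's climate, in realm-sd units.
    """

    breadth_range: tuple[float, float] = (0.6, 1.2)
    threshold_range: tuple[float, float] = (0.2, 0.5)
    optimum_jitter: float = 0.15
    #: realized ranges are capped at this fraction of the realm so that the
    #: background can always supply three pseudoabsences per presence
    max_presence_frac: float = 0.2
    max_retries: int = 200


@dataclass
class VirtualSpecies:
    """A species with a known Gaussian niche over the five bioclim variables."""

    species_id: str
    realm: str
    family: str
    status: str
    mu: np.ndarray  # (5,) niche optimum, BIOCLIM_VARS order
    sigma: np.ndarray  # (5,) niche breadth, > 0
    suitability_threshold: float  # s* in (0, 1)
    presence_cells: np.ndarray  # sorted cell ids, >= 50 of them

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("niche breadths must be positive")
        if not (0.0 < self.suitability_threshold < 1.0):
            raise ValueError("suitability threshold must lie in (0, 1)")
        self.presence_cells = np.sort(np.asarray(self.presence_cells, dtype=int))

    def suitability(self, stack: BioclimStack, cell_ids: np.ndarray | None = None) -> np.ndarray:
        """True suitability s(x) = exp(-sum_v (x_v - mu_v)^2 / (2 sigma_v^2))."""
        x = stack.features(cell_ids)
        z2 = ((x - self.mu) / self.sigma) ** 2
        return np.exp(-0.5 * z2.sum(axis=1))


def _realm_stats(stack: BioclimStack, cells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = stack.features(cells)
    sd = x.std(axis=0, ddof=1)
    # floor avoids zero-width niches on climatically flat realms
    sd = np.maximum(sd, 1e-3 + 0.02 * np.abs(x.mean(axis=0)))
    return x.mean(axis=0), sd


def generate_virtual_species(
    world: WorldRealization,
    n_species: int,
    niche_spec: NicheSpec | None = None,
    seed: int | None = None,
    min_presence: int = 50,
) -> list[VirtualSpecies]:
    """Draw virtual species with known niches and >= ``min_presence`` cells.

    Species are assigned to realms round-robin.  Each niche is anchored at a
    randomly chosen cell of the realm (jittered in climate space) with
    breadths proportional to the realm's climatic spread; candidates whose
    realized range (suitability >= s* within the realm) falls below the
    minimum presence size are redrawn, up to ``niche_spec.max_retries``
    attempts per species.
    """
    niche_spec = niche_spec or NicheSpec()
    seed = world.spec.seed if seed is None else seed
    stack = world.baseline_bioclim()
    realm_mask = world.realm_mask
    rng = np.random.default_rng(derived_seed(seed, "virtual_species"))

    realm_cells = {name: realm_mask.cells_for(name) for name in realm_mask.names}
    realm_stat = {name: _realm_stats(stack, cells) for name, cells in realm_cells.items()}

    species: list[VirtualSpecies] = []
    for i in range(n_species):
        realm = realm_mask.names[i % realm_mask.n_realms]
        cells = realm_cells[realm]
        _, realm_sd = realm_stat[realm]
        feats = stack.features(cells)
        ok = False
        for _ in range(niche_spec.max_retries):
            anchor = feats[rng.integers(len(cells))]
            mu = anchor + rng.normal(0.0, niche_spec.optimum_jitter, 5) * realm_sd
            breadth = rng.uniform(*niche_spec.breadth_range, size=5)
            sigma = np.maximum(breadth * realm_sd, 1e-6)
            s_star = float(rng.uniform(*niche_spec.threshold_range))
            s = np.exp(-0.5 * (((feats - mu) / sigma) ** 2).sum(axis=1))
            presence = cells[s >= s_star]
            if min_presence <= len(presence) <= niche_spec.max_presence_frac * len(cells):
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"could not place a species with >= {min_presence} presence "
                f"cells in realm {realm!r} after {niche_spec.max_retries} tries"
            )
        species.append(
            VirtualSpecies(
                species_id=f"vsp{i:04d}",
                realm=realm,
                family=f"Fam{(i // realm_mask.n_realms) % 12:02d}",
                status=str(rng.choice(IUCN_STATUSES, p=_STATUS_WEIGHTS)),
                mu=mu,
                sigma=sigma,
                suitability_threshold=s_star,
                presence_cells=presence,
            )
        )
    return species


def true_range_change(
    species: VirtualSpecies,
    future_bioclim: BioclimStack,
    dispersal: str,
    realm_mask: RealmMask,
) -> float:
    """Oracle range change q = (p1 - p2) / p1 from the species' true niche.

    The true current range is the species' presence cell set; the future
    range applies the same suitability function and threshold s* to the
    future bioclim stack, restricted to the species' realm.  Under no
    dispersal the future range is intersected with the current one.
    """
    if dispersal not in ("full", "none"):
        raise ValueError(f"dispersal must be 'full' or 'none', got {dispersal!r}")
    current = species.presence_cells
    p1 = len(current)
    if p1 == 0:
        raise RangeUndefinedError(f"{species.species_id}: empty current range")
    realm_cells = realm_mask.cells_for(species.realm)
    s = species.suitability(future_bioclim, realm_cells)
    future = realm_cells[s >= species.suitability_threshold]
    if dispersal == "none":
        future = np.intersect1d(future, current, assume_unique=True)
    p2 = len(future)
    return (p1 - p2) / p1
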