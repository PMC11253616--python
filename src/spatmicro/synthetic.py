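"""Synthetic labeled point patterns emulating a multiplexed-FISH study.

Generates cell tables with known ground truth so that every downstream
stage (diversity, colocalization, mark-equality, neighborhood, keystone
screening) can be tested without real images. The generator emulates:

* 135 x 135 µm fields of view with a ~60-taxon panel and strongly skewed
  (log-normal) relative abundances;
* conspecific micro-clustering at the few-µm scale via a Thomas-type
  parent/offspring process (bacteria do not move far after division);
* planted cross-taxon attraction or repulsion at a short interaction
  range, by relocating a fraction of one taxon's cells near (or away
  from) its partner;
* antibiotic perturbation: survival multipliers knocking most taxa down
  with one-to-two-taxon blooms, and partial recovery at a later day
  whose quality is driven by a planted keystone taxon's mouse-level
  baseline abundance;
* the nested study design (tissue x treatment x day x mouse x FoV).

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` keyed by the image context, so any
image can be regenerated independently and the full study is
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import DEFAULT_FOV_UM, make_panel

__all__ = [
    "ConfigError",
    "Clustering",
    "Attraction",
    "Perturbation",
    "DesignCell",
    "SimulationConfig",
    "GroundTruth",
    "default_config",
    "scaled_config",
    "simulate_image",
    "simulate_study",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class Clustering:
    """Same-species clumping parameters for one taxon.

    ``offspring_mean`` is the expected number of cells per parent
    (clump); ``dispersion_sigma_um`` the isotropic Gaussian spread of
    offspring around the parent. ``offspring_mean <= 1`` degenerates to a
    homogeneous Poisson process. ``cluster_rate`` (parents per µm²), if
    given, overrides the abundance-derived parent intensity.
    """

    offspring_mean: float = 5.0
    dispersion_sigma_um: float = 1.5
    cluster_rate: float | None = None


@dataclass(frozen=True)
class Attraction:
    """Planted pairwise interaction: phi>1 attraction, phi<1 repulsion.

    A fraction |phi - 1| / max(phi, 1) of taxon_b's cells is relocated
    within (phi>1) or away from (phi<1) ``rho_um`` of taxon_a cells.
    ``knockout_treatments`` lists treatments under which the interaction
    is absent from day 0 onward (an interaction destroyed by the
    antibiotic and not recovered).
    """

    taxon_a: int
    taxon_b: int
    phi: float = 1.0
    rho_um: float = 3.0
    knockout_treatments: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Perturbation:
    """Abundance multipliers for one (treatment, day).

    Expected count of taxon t is scaled by
    ``taxon_multipliers.get(t, default_survival)``; bloom taxa carry
    multipliers > 1. Baseline days must not appear here.
    """

    treatment: str
    day: int
    default_survival: float = 1.0
    taxon_multipliers: Mapping[int, float] = field(default_factory=dict)

    def multiplier(self, taxon: int) -> float:
        return float(self.taxon_multipliers.get(taxon, self.default_survival))


@dataclass(frozen=True)
class DesignCell:
    tissue: str
    treatment: str
    day: int
    n_mice: int = 3
    n_fov: int = 12  # per mouse (3 sections x 4 FoV)


@dataclass
class SimulationConfig:
    """Full ground-truth parameterization of a synthetic study."""

    seed: int = 0
    n_taxa: int = 60
    fov_um: tuple[float, float] = DEFAULT_FOV_UM
    design: Sequence[DesignCell] = field(default_factory=list)
    # log-normal relative-abundance draw (location 0, this sigma), or an
    # explicit per-taxon weight vector
    abundance_sigma: float = 1.5
    base_abundance: Sequence[float] | None = None
    total_cells_mean: float = 1500.0
    default_clustering: Clustering = field(default_factory=Clustering)
    clustering: Mapping[int, Clustering] = field(default_factory=dict)
    attraction: Sequence[Attraction] = field(default_factory=list)
    perturbation: Sequence[Perturbation] = field(default_factory=list)
    # per-mouse log-normal abundance jitter (cage effects); per-taxon override
    mouse_jitter_sigma: float = 0.3
    taxon_jitter_sigma: Mapping[int, float] = field(default_factory=dict)
    # per-image log-normal total-intensity jitter
    fov_jitter_sigma: float = 0.15
    # microhabitat hotspots: dense mixed-community discs (digesta-like
    # regions) that taxa occupy with taxon-specific affinity. A taxon
    # with high affinity places that fraction of its cells (or clump
    # parents) inside hotspots, giving it dense, diverse neighborhoods.
    # hotspot_count = 0 (default) disables the mechanism entirely.
    hotspot_count: int = 0
    hotspot_radius_um: float = 10.0
    default_hotspot_affinity: float = 0.3
    hotspot_affinity: Mapping[int, float] = field(default_factory=dict)
    baseline_day: int = -8
    recovery_day: int = 35
    # driver-taxon recovery: at the recovery day the composition is a
    # mixture w * baseline + (1 - w) * perturbed, with w increasing in
    # the mouse's baseline abundance multipliers of the driver taxa
    # (defaults to the keystone taxon when unset)
    keystone_taxon: int | None = None
    foundation_taxa: Sequence[int] = field(default_factory=list)
    recovery_driver_taxa: Sequence[int] | None = None
    recovery_sharpness: float = 1.0
    # the recovering community converges toward a driver-enriched
    # rebuild state: at the recovery day the non-recovered residual is a
    # mix of the perturbed composition and the global baseline with the
    # driver taxa boosted by this factor
    driver_rebuild_boost: float = 4.0
    # the keystone's contribution to the rebuild state is
    # disproportionate to its abundance (that is what makes it keystone)
    keystone_rebuild_boost: float = 18.0
    rebuild_fraction: float = 0.85

    def validate(self) -> None:
        if not self.design:
            raise ConfigError("design contains no images")
        for p in self.perturbation:
            if p.day == self.baseline_day:
                raise ConfigError("perturbation must not apply at the baseline day")
            if p.default_survival < 0 or any(m < 0 for m in p.taxon_multipliers.values()):
                raise ConfigError("survival multipliers must be nonnegative")
        if self.base_abundance is not None and len(self.base_abundance) != self.n_taxa:
            raise ConfigError("base_abundance length must equal n_taxa")

    def clustering_for(self, taxon: int) -> Clustering:
        return self.clustering.get(taxon, self.default_clustering)

    def jitter_sigma_for(self, taxon: int) -> float:
        return float(self.taxon_jitter_sigma.get(taxon, self.mouse_jitter_sigma))

    def affinity_for(self, taxon: int) -> float:
        return float(self.hotspot_affinity.get(taxon, self.default_hotspot_affinity))

    def driver_taxa(self) -> list[int]:
        if self.recovery_driver_taxa is not None:
            return list(self.recovery_driver_taxa)
        return [] if self.keystone_taxon is None else [self.keystone_taxon]

    def perturbation_for(self, treatment: str, day: int) -> Perturbation | None:
        for p in self.perturbation:
            if p.treatment == treatment and p.day == day:
                return p
        return None


@dataclass
class GroundTruth:
    """Planted truth emitted alongside a simulated study.

    Never read by analysis code; used only to verify recovery of planted
    effects in tests.
    """

    base_abundance: np.ndarray
    realized_abundance: pd.DataFrame  # image x taxon cell counts
    attractions: list[Attraction]
    keystone_taxon: int | None
    foundation_taxa: list[int]
    mouse_multipliers: pd.DataFrame  # mouse x taxon jitter multipliers
    recovery_weights: dict[str, float]  # mouse_id -> mixing weight w


# ---------------------------------------------------------------- defaults

def default_config(seed: int = 0) -> SimulationConfig:
    """The full study design: 2 tissues x 3 treatments x 3 days x 3 mice x 12 FoV.

    Ampicillin leaves two bloom taxa dominating at day 0; vancomycin one
    (over 95% of cells). Taxon 1 and 2 are abundant, dispersed foundation
    taxa; the last taxon is a rare, dispersed keystone whose mouse-level
    baseline abundance drives recovery quality. One attraction pair
    (3, 4) is planted and knocked out by ampicillin.
    """
    days = (-8, 0, 35)
    design = [
        DesignCell(tissue, treatment, day)
        for tissue in ("cecum", "colon")
        for treatment in ("water", "ampicillin", "vancomycin")
        for day in days
    ]
    n_taxa = 60
    keystone = n_taxa - 1
    perturbation = []
    for treatment, blooms in (("ampicillin", {5: 40.0, 6: 25.0}), ("vancomycin", {7: 120.0})):
        perturbation.append(Perturbation(treatment, 0, default_survival=0.02,
                                         taxon_multipliers=blooms))
    dispersed = Clustering(offspring_mean=1.0, dispersion_sigma_um=1.5)
    return SimulationConfig(
        seed=seed,
        n_taxa=n_taxa,
        design=design,
        perturbation=perturbation,
        clustering={1: dispersed, 2: dispersed, keystone: dispersed},
        attraction=[Attraction(3, 4, phi=5.0, rho_um=3.0,
                               knockout_treatments=frozenset({"ampicillin"}))],
        keystone_taxon=keystone,
        foundation_taxa=[1, 2],
        recovery_driver_taxa=[1, 2, keystone],
        taxon_jitter_sigma={1: 0.5, 2: 0.5, keystone: 0.5},
        hotspot_count=5,
        hotspot_affinity={1: 0.75, 2: 0.75, keystone: 0.75},
    )


def scaled_config(seed: int = 0, n_taxa: int = 12, n_mice: int = 6,
                  n_fov: int = 6, total_cells_mean: float = 600.0,
                  tissues: Sequence[str] = ("cecum",)) -> SimulationConfig:
    """A reduced study retaining every planted effect, for fast end-to-end runs.

    One or two tissues, water + ampicillin, baseline and recovery days
    only (36 images per group, as in the full design). Taxa 1 and 2 are
    abundant dispersed foundation taxa, the last taxon the rare
    dispersed keystone; all three occupy the dense microhabitat hotspots
    (hence high neighborhood richness) and drive recovery. The
    attraction pair (3, 4) is knocked out by ampicillin. Explicit base
    abundances keep the conditions identical across seeds.
    """
    if n_taxa < 8:
        raise ConfigError("scaled study needs at least 8 taxa")
    keystone = n_taxa - 1
    design = [
        DesignCell(tissue, treatment, day, n_mice=n_mice, n_fov=n_fov)
        for tissue in tissues
        for treatment in ("water", "ampicillin")
        for day in (-8, 35)
    ]
    weights = np.full(n_taxa, 2.0)
    weights[0] = 6.0
    weights[1], weights[2] = 9.0, 8.0  # foundation: abundant, hotspot hubs
    weights[3] = weights[4] = 7.0  # attracted pair, clumped outside hotspots
    weights[5] = 5.0  # bloom survivor, hotspot occupant
    weights[6], weights[7] = 4.0, 3.0
    weights[keystone] = 2.0  # rare keystone hub
    dispersed = Clustering(offspring_mean=1.0, dispersion_sigma_um=1.5)
    return SimulationConfig(
        seed=seed,
        n_taxa=n_taxa,
        design=design,
        base_abundance=weights.tolist(),
        total_cells_mean=total_cells_mean,
        perturbation=[Perturbation("ampicillin", 0, default_survival=0.02,
                                   taxon_multipliers={5: 40.0})],
        clustering={1: dispersed, 2: dispersed, keystone: dispersed},
        attraction=[Attraction(3, 4, phi=5.0, rho_um=3.0,
                               knockout_treatments=frozenset({"ampicillin"}))],
        keystone_taxon=keystone,
        foundation_taxa=[1, 2],
        recovery_driver_taxa=[1, 2, keystone],
        mouse_jitter_sigma=0.15,
        taxon_jitter_sigma={1: 0.4, 2: 0.4, keystone: 0.7},
        hotspot_count=5,
        hotspot_affinity={1: 0.85, 2: 0.85, keystone: 0.85, 5: 0.6,
                         3: 0.05, 4: 0.05},
    )


# ------------------------------------------------------------ RNG plumbing

_TISSUE_KEY = {"cecum": 1, "colon": 2}
_TREATMENT_KEY = {"water": 1, "ampicillin": 2, "vancomycin": 3}


def _image_rng(config: SimulationConfig, tissue: str, treatment: str, day: int,
               mouse: int, fov: int) -> np.random.Generator:
    key = [int(config.seed), 11,
           _TISSUE_KEY.get(tissue, 97 + hash(tissue) % 1000),
           _TREATMENT_KEY.get(treatment, 97 + hash(treatment) % 1000),
           int(day) + 1000, int(mouse), int(fov)]
    return np.random.default_rng(np.random.SeedSequence(key))


def _mouse_rng(config: SimulationConfig, treatment: str, mouse: int) -> np.random.Generator:
    key = [int(config.seed), 23,
           _TREATMENT_KEY.get(treatment, 97 + hash(treatment) % 1000), int(mouse)]
    return np.random.default_rng(np.random.SeedSequence(key))


def _base_abundance(config: SimulationConfig) -> np.ndarray:
    if config.base_abundance is not None:
        w = np.asarray(config.base_abundance, dtype=float)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 5]))
        w = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=config.n_taxa)
        # make planted foundation taxa genuinely abundant and the keystone rare
        for t in config.foundation_taxa:
            w[t] = np.quantile(w, 0.98) * (1.2 + 0.2 * (t % 3))
        if config.keystone_taxon is not None:
            w[config.keystone_taxon] = np.quantile(w, 0.35)
    if (w < 0).any() or w.sum() <= 0:
        raise ConfigError("base abundances must be nonnegative with positive sum")
    return w / w.sum()


def _mouse_multipliers(config: SimulationConfig, treatment: str, mouse: int) -> np.ndarray:
    rng = _mouse_rng(config, treatment, mouse)
    sig = np.array([config.jitter_sigma_for(t) for t in range(config.n_taxa)])
    return np.exp(rng.normal(0.0, 1.0, size=config.n_taxa) * sig)


def _recovery_weight(config: SimulationConfig, base_p: np.ndarray,
                     treatment: str, mouse: int) -> float:
    """Mixing weight toward baseline at the recovery day for one mouse.

    A saturating function of the geometric mean of the mouse's jitter
    multipliers over the driver taxa: mice that start with more of the
    drivers recover closer to their baseline composition.
    """
    drivers = config.driver_taxa()
    if not drivers:
        return 0.5
    mult = _mouse_multipliers(config, treatment, mouse)[drivers]
    s = float(np.exp(np.log(mult).mean())) ** config.recovery_sharpness
    return float(s / (s + 1.0))


def _expected_counts(config: SimulationConfig, base_p: np.ndarray,
                     treatment: str, day: int, mouse: int) -> np.ndarray:
    """Expected per-taxon cell counts for one image (before FoV jitter)."""
    mult = _mouse_multipliers(config, treatment, mouse)
    comp = base_p * mult
    comp = comp / comp.sum() * config.total_cells_mean

    if day == config.baseline_day:
        return comp

    pert = config.perturbation_for(treatment, 0)
    if pert is None:  # water/control: composition is stable across days
        return comp
    survivors = comp * np.array([pert.multiplier(t) for t in range(config.n_taxa)])

    if day == 0:
        return survivors  # load drops with the community

    if day == config.recovery_day:
        # load recovers; composition is a mixture of (a) the mouse's own
        # baseline, weighted by its recovery quality, and (b) a residual
        # blending the perturbed state with the driver-enriched rebuild
        # state every recovering community converges toward
        w = _recovery_weight(config, base_p, treatment, mouse)
        surv_comp = survivors / survivors.sum() if survivors.sum() > 0 else survivors
        rebuild = base_p.copy()
        drivers = config.driver_taxa()
        if drivers:
            rebuild[drivers] *= config.driver_rebuild_boost
            if config.keystone_taxon is not None:
                rebuild[config.keystone_taxon] = (
                    base_p[config.keystone_taxon] * config.keystone_rebuild_boost)
            rebuild = rebuild / rebuild.sum()
        resid = ((1 - config.rebuild_fraction) * surv_comp
                 + config.rebuild_fraction * rebuild)
        mix = w * comp / comp.sum() + (1 - w) * resid
        return mix * config.total_cells_mean

    return comp


# ----------------------------------------------------------- point placement

def _sample_positions(rng: np.random.Generator, n: int, fov: tuple[float, float],
                      hotspots: np.ndarray | None, radius: float,
                      affinity: float) -> np.ndarray:
    """Uniform positions, a fraction ``affinity`` of them inside hotspot discs."""
    w, h = fov
    pts = rng.uniform([0, 0], [w, h], size=(n, 2))
    if hotspots is None or len(hotspots) == 0 or affinity <= 0:
        return pts
    in_hot = rng.uniform(size=n) < affinity
    for i in np.where(in_hot)[0]:
        center = hotspots[rng.integers(0, len(hotspots))]
        for _ in range(200):  # disc may cross the window boundary
            r = radius * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            cand = center + [r * np.cos(th), r * np.sin(th)]
            if 0 <= cand[0] <= w and 0 <= cand[1] <= h:
                pts[i] = cand
                break
    return pts


def _place_taxon(rng: np.random.Generator, lam: float, clustering: Clustering,
                 fov: tuple[float, float], hotspots: np.ndarray | None = None,
                 hotspot_radius: float = 10.0, affinity: float = 0.0) -> np.ndarray:
    """Thomas-type placement of one taxon; returns an (n, 2) array."""
    w, h = fov
    area = w * h
    mu = max(clustering.offspring_mean, 1e-9)
    if clustering.offspring_mean <= 1.0:
        n = rng.poisson(lam)
        return _sample_positions(rng, n, fov, hotspots, hotspot_radius, affinity)
    if clustering.cluster_rate is not None:
        n_parents = rng.poisson(clustering.cluster_rate * area)
    else:
        n_parents = rng.poisson(lam / mu)
    if n_parents == 0:
        return np.empty((0, 2))
    parents = _sample_positions(rng, n_parents, fov, hotspots, hotspot_radius, affinity)
    counts = rng.poisson(mu, size=n_parents)
    pts = []
    sigma = clustering.dispersion_sigma_um
    for p, k in zip(parents, counts):
        if k == 0:
            continue
        got = np.empty((0, 2))
        # conditional simulation: redraw displacements until inside the window
        while len(got) < k:
            cand = p + rng.normal(0.0, sigma, size=(k - len(got), 2))
            ok = (cand[:, 0] >= 0) & (cand[:, 0] <= w) & (cand[:, 1] >= 0) & (cand[:, 1] <= h)
            got = np.vstack([got, cand[ok]])
        pts.append(got)
    return np.vstack(pts) if pts else np.empty((0, 2))


def _apply_attraction(rng: np.random.Generator, points: dict[int, np.ndarray],
                      att: Attraction, fov: tuple[float, float]) -> None:
    """Relocate a fraction of taxon_b cells relative to taxon_a cells."""
    a_pts = points.get(att.taxon_a)
    b_pts = points.get(att.taxon_b)
    if a_pts is None or b_pts is None or len(a_pts) == 0 or len(b_pts) == 0:
        return
    w, h = fov
    phi = att.phi
    if phi == 1.0:
        return
    frac = abs(phi - 1.0) / max(phi, 1.0)
    n_move = int(round(frac * len(b_pts)))
    if n_move == 0:
        return
    idx = rng.choice(len(b_pts), size=n_move, replace=False)
    if phi > 1.0:
        anchors = a_pts[rng.integers(0, len(a_pts), size=n_move)]
        for j, anchor in zip(idx, anchors):
            for _ in range(200):
                r = att.rho_um * np.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * np.pi)
                cand = anchor + [r * np.cos(th), r * np.sin(th)]
                if 0 <= cand[0] <= w and 0 <= cand[1] <= h:
                    b_pts[j] = cand
                    break
    else:
        from scipy.spatial import cKDTree

        tree = cKDTree(a_pts)
        for j in idx:
            for _ in range(200):
                cand = rng.uniform([0, 0], [w, h])
                if tree.query(cand, k=1)[0] > att.rho_um:
                    b_pts[j] = cand
                    break


def simulate_image(
    config: SimulationConfig,
    tissue: str,
    treatment: str,
    day: int,
    mouse: int = 0,
    fov: int = 0,
    image_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one field of view; returns a CellTable DataFrame.

    An empty image (all intensities zero) is valid output.
    """
    if rng is None:
        rng = _image_rng(config, tissue, treatment, day, mouse, fov)
    if image_id is None:
        image_id = f"{tissue}_{treatment}_d{day}_m{mouse}_f{fov}"
    base_p = _base_abundance(config)
    lam = _expected_counts(config, base_p, treatment, day, mouse)
    if config.fov_jitter_sigma > 0:
        lam = lam * rng.lognormal(-config.fov_jitter_sigma**2 / 2, config.fov_jitter_sigma)

    hotspots = None
    if config.hotspot_count > 0:
        hotspots = rng.uniform([0, 0], list(config.fov_um),
                               size=(config.hotspot_count, 2))

    points: dict[int, np.ndarray] = {}
    for t in range(config.n_taxa):
        if lam[t] <= 0:
            continue
        pts = _place_taxon(rng, float(lam[t]), config.clustering_for(t),
                           config.fov_um, hotspots, config.hotspot_radius_um,
                           config.affinity_for(t))
        if len(pts):
            points[t] = pts

    for att in config.attraction:
        active = not (treatment in att.knockout_treatments and day > config.baseline_day)
        if active:
            _apply_attraction(rng, points, att, config.fov_um)

    rows = []
    for t in sorted(points):
        for x, y in points[t]:
            rows.append((image_id, float(x), float(y), int(t)))
    return pd.DataFrame(rows, columns=["image_id", "x_um", "y_um", "taxon_id"])


def simulate_study(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the full factorial study.

    Returns (cells, metadata, ground_truth). The same seed yields
    byte-identical outputs.
    """
    config.validate()
    base_p = _base_abundance(config)
    cells_parts, meta_rows = [], []
    mouse_mult_rows = {}
    recovery_weights = {}
    for cell in config.design:
        for mouse in range(cell.n_mice):
            mouse_id = f"{cell.treatment}_m{mouse}"
            mouse_mult_rows[mouse_id] = _mouse_multipliers(config, cell.treatment, mouse)
            recovery_weights[mouse_id] = _recovery_weight(config, base_p, cell.treatment, mouse)
            for fov_idx in range(cell.n_fov):
                section, fov_in_section = fov_idx // 4 + 1, fov_idx % 4 + 1
                image_id = (f"{cell.tissue}_{cell.treatment}_d{cell.day}"
                            f"_m{mouse}_s{section}_f{fov_in_section}")
                img = simulate_image(config, cell.tissue, cell.treatment, cell.day,
                                     mouse=mouse, fov=fov_idx, image_id=image_id)
                cells_parts.append(img)
                meta_rows.append({
                    "image_id": image_id,
                    "mouse_id": mouse_id,
                    "tissue": cell.tissue,
                    "treatment": cell.treatment,
                    "day": cell.day,
                    "section": section,
                    "fov": fov_in_section,
                    "fov_width_um": config.fov_um[0],
                    "fov_height_um": config.fov_um[1],
                })
    cells_parts = [p for p in cells_parts if len(p)]
    cells = pd.concat(cells_parts, ignore_index=True) if cells_parts else pd.DataFrame(
        columns=["image_id", "x_um", "y_um", "taxon_id"])
    meta = pd.DataFrame(meta_rows)

    realized = (
        cells.groupby(["image_id", "taxon_id"]).size().unstack(fill_value=0)
        .reindex(index=list(meta["image_id"]), columns=range(config.n_taxa), fill_value=0)
        .astype(np.int64)
    )
    realized.index.name = "image_id"
    truth = GroundTruth(
        base_abundance=base_p,
        realized_abundance=realized,
        attractions=list(config.attraction),
        keystone_taxon=config.keystone_taxon,
        foundation_taxa=list(config.foundation_taxa),
        mouse_multipliers=pd.DataFrame(mouse_mult_rows).T,
        recovery_weights=recovery_weights,
    )
    return cells, meta, truth


def panel_for(config: SimulationConfig) -> pd.DataFrame:
    """TaxonPanel matching a simulation config."""
    return make_panel(range(config.n_taxa))


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON/YAML-serializable echo of a config (for run manifests)."""
    d = dataclasses.asdict(config)
    d["attraction"] = [
        {**dataclasses.asdict(a), "knockout_treatments": sorted(a.knockout_treatments)}
        for a in config.attraction
    ]
    return d
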