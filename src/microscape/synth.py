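"""Seeded synthetic tissues and microregion count matrices with ground truth.

Tissues emulate the statistical structure the analysis assumes: spatially
nested tumor domains with infiltrating immune cells, endothelial cells along
vessel corridors, debris-flagged necrotic zones at reduced density,
gate-separable two-component log-normal marker intensities, and cell-cycle
states that emit ordered marker co-expression (G1/S -> S adds CCNA2 ->
G2/M adds CCNB1 -> M adds pH3; arrested/quiescent cells express p21/p27).

Microregion count matrices are negative-binomial with per-gene base means;
genes belonging to "active" sets receive a multiplicative mean shift scaled
by a per-microregion latent activity, optionally correlated between two
signatures within one compartment only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError
from .gating import GateConfig, GateEntry
from .signatures import GeneSet

TRUTH_PREFIX = "true_"

CELLCYCLE_MARKERS: dict[str, frozenset] = {
    "g1s": frozenset({"KI67"}),
    "s": frozenset({"KI67", "CCNA2"}),
    "g2m": frozenset({"KI67", "CCNA2", "CCNB1"}),
    "m": frozenset({"KI67", "CCNA2", "CCNB1", "pH3"}),
    # arrested cells keep expressing KI67 (arrest dominates downstream)
    "arrested": frozenset({"KI67", "p21"}),
    "quiescent": frozenset({"p21", "p27"}),
    "none": frozenset(),
}

ARREST_STATES = frozenset({"arrested", "quiescent"})

DEFAULT_MARKERS = (
    "SOX10", "PMEL", "CD45", "CD3E", "CD8A", "CD4", "FOXP3",
    "CD68", "CD163", "CD206", "CD11C", "CD31",
    "KI67", "CCNA2", "CCNB1", "pH3", "p21", "p27",
    "GZMB", "PD1", "LAG3", "TIM3", "CD45RO", "CD45RA", "LEF1", "CD103",
)


def _check_mixture(name: str, mix: Mapping[str, float]) -> None:
    vals = np.array(list(mix.values()), dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ConfigurationError(f"{name}: proportions must lie in [0, 1]")
    if vals.size and not math.isclose(vals.sum(), 1.0, abs_tol=1e-9):
        raise ConfigurationError(f"{name}: proportions must sum to 1, got {vals.sum()}")


@dataclass(frozen=True)
class MarkerParams:
    """Two-component log-normal intensity model for one marker.

    Locations/scales are on the natural-log intensity scale; the positive
    (expression) component must sit strictly above the negative
    (autofluorescence) component.
    """

    neg_mu: float
    pos_mu: float
    neg_sigma: float = 0.4
    pos_sigma: float = 0.4

    def __post_init__(self):
        if self.pos_mu <= self.neg_mu:
            raise ConfigurationError(
                f"positive component location ({self.pos_mu}) must exceed the "
                f"negative component location ({self.neg_mu})"
            )
        if self.neg_sigma <= 0 or self.pos_sigma <= 0:
            raise ConfigurationError("component scales must be positive")

    @property
    def gate_intensity(self) -> float:
        """Midpoint of the two components on the log scale -> true gate."""
        return math.exp(0.5 * (self.neg_mu + self.pos_mu))

    def gate_entry(self) -> GateEntry:
        return GateEntry(
            low=math.exp(self.neg_mu - 2.0 * self.neg_sigma),
            gate=self.gate_intensity,
            high=math.exp(self.pos_mu + 2.0 * self.pos_sigma),
        )


@dataclass
class DomainSpec:
    """One macroscopic tissue domain.

    ``nests``: (cx, cy, radius) tumor nests in μm; ``region`` is the
    axis-aligned rectangle (x0, y0, x1, y1) the domain's cells occupy
    (defaults to the whole field); ``vessels`` are polylines along which
    endothelial cells are placed.
    """

    domain_id: str
    nests: Sequence[tuple]
    tumor_fraction: float
    immune_mix: Mapping[str, float]
    necrosis: bool = False
    vessels: Sequence[Sequence[tuple]] = ()
    region: tuple | None = None
    weight: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ConfigurationError("tumor_fraction must lie in [0, 1]")
        _check_mixture(f"domain {self.domain_id} immune_mix", self.immune_mix)
        if self.weight <= 0:
            raise ConfigurationError("domain weight must be positive")
        if self.tumor_fraction > 0 and not self.nests:
            raise ConfigurationError(
                f"domain {self.domain_id} has tumor cells but no nests"
            )


@dataclass
class TissueConfig:
    """Full specification of one synthetic tissue; ``seed`` is mandatory."""

    n_cells: int
    field_size: tuple
    domains: Sequence[DomainSpec]
    marker_model: Mapping[str, MarkerParams]
    class_signatures: Mapping[str, frozenset]
    cellcycle_mix: Mapping[str, float]
    seed: int
    vessel_halfwidth: float = 10.0
    necrosis_thinning: float = 0.2
    necrosis_band: float = 50.0  # wedge depth; keep <= the peritumoral band

    def __post_init__(self):
        if self.n_cells == 0:
            raise EmptyInputError("n_cells must be positive (empty table requested)")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be positive")
        w, h = self.field_size
        if w <= 0 or h <= 0:
            raise ConfigurationError("field_size must be positive")
        if not self.domains:
            raise ConfigurationError("at least one domain is required")
        _check_mixture("cellcycle_mix", self.cellcycle_mix)
        unknown = set(self.cellcycle_mix) - set(CELLCYCLE_MARKERS)
        if unknown:
            raise ConfigurationError(f"unknown cell-cycle states: {sorted(unknown)}")
        for cls, sig in self.class_signatures.items():
            missing = set(sig) - set(self.marker_model)
            if missing:
                raise ConfigurationError(
                    f"class {cls!r} references unmodeled markers: {sorted(missing)}"
                )


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated artifact.

    For tissues: per-cell labels (class, cell-cycle state, region, domain,
    debris flag), a per-cell/per-marker true-positivity frame, and the true
    gates.  For count matrices: per-microregion compartment and latent
    activities.
    """

    cells: pd.DataFrame | None = None
    positivity: pd.DataFrame | None = None
    gates: GateConfig | None = None
    microregions: pd.DataFrame | None = None


def default_class_signatures() -> dict[str, frozenset]:
    cd8 = frozenset({"CD45", "CD3E", "CD8A"})
    return {
        "Tumor": frozenset({"SOX10", "PMEL"}),
        "naive CD8 T": cd8 | {"LEF1", "CD45RA"},
        "memory CD8 T": cd8 | {"CD45RO"},
        "resident memory CD8 T": cd8 | {"CD45RO", "CD103"},
        "cytotoxic CD8 T": cd8 | {"GZMB"},
        "proliferative cytotoxic CD8 T": cd8 | {"GZMB", "KI67"},
        "partially exhausted CD8 T": cd8 | {"PD1", "LAG3"},
        "terminally exhausted CD8 T": cd8 | {"PD1", "LAG3", "TIM3"},
        "Treg": frozenset({"CD45", "CD3E", "CD4", "FOXP3"}),
        "CD4 T": frozenset({"CD45", "CD3E", "CD4"}),
        "Macrophage": frozenset({"CD45", "CD68", "CD163", "CD206"}),
        "Myeloid": frozenset({"CD45", "CD11C"}),
        "Endothelial": frozenset({"CD31"}),
    }


ENDOTHELIAL_CLASS = "Endothelial"


def default_marker_model(
    markers: Sequence[str] = DEFAULT_MARKERS,
    neg_mu: float = 4.0,
    pos_mu: float = 6.5,
    sigma: float = 0.4,
) -> dict[str, MarkerParams]:
    return {m: MarkerParams(neg_mu, pos_mu, sigma, sigma) for m in markers}


def default_cellcycle_mix() -> dict[str, float]:
    return {"g1s": 0.10, "s": 0.05, "g2m": 0.05, "m": 0.02,
            "arrested": 0.08, "quiescent": 0.12, "none": 0.58}


def default_immune_mix() -> dict[str, float]:
    return {
        "naive CD8 T": 0.05,
        "memory CD8 T": 0.08,
        "resident memory CD8 T": 0.05,
        "cytotoxic CD8 T": 0.10,
        "proliferative cytotoxic CD8 T": 0.04,
        "partially exhausted CD8 T": 0.05,
        "terminally exhausted CD8 T": 0.03,
        "Treg": 0.08,
        "CD4 T": 0.14,
        "Macrophage": 0.16,
        "Myeloid": 0.12,
        "Endothelial": 0.10,
    }


def default_tissue_config(
    n_cells: int = 5000,
    seed: int = 0,
    tumor_fraction: float = 0.4,
    field_size: tuple = (2000.0, 2000.0),
    necrosis: bool = True,
) -> TissueConfig:
    """A two-domain demonstration tissue with nests, a vessel, and necrosis."""
    w, h = field_size
    domains = [
        DomainSpec(
            domain_id="A",
            nests=[(w * 0.25, h * 0.3, 220.0), (w * 0.3, h * 0.65, 160.0)],
            tumor_fraction=tumor_fraction,
            immune_mix=default_immune_mix(),
            necrosis=necrosis,
            vessels=[[(w * 0.05, h * 0.85), (w * 0.45, h * 0.9)]],
            region=(0.0, 0.0, w * 0.5, h),
        ),
        DomainSpec(
            domain_id="B",
            nests=[(w * 0.75, h * 0.5, 200.0)],
            tumor_fraction=tumor_fraction,
            immune_mix=default_immune_mix(),
            vessels=[[(w * 0.55, h * 0.15), (w * 0.95, h * 0.1)]],
            region=(w * 0.5, 0.0, w, h),
        ),
    ]
    return TissueConfig(
        n_cells=n_cells,
        field_size=field_size,
        domains=domains,
        marker_model=default_marker_model(),
        class_signatures=default_class_signatures(),
        cellcycle_mix=default_cellcycle_mix(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# geometry helpers


def _point_in_disk(rng, cx, cy, radius, n):
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * np.pi
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def _sample_on_polyline(rng, polyline, halfwidth, n):
    pts = np.asarray(polyline, dtype=float)
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    probs = seg_len / seg_len.sum()
    idx = rng.choice(len(seg), size=n, p=probs)
    t = rng.random(n)
    base = pts[idx] + t[:, None] * seg[idx]
    unit = seg[idx] / seg_len[idx][:, None]
    normal = np.column_stack([-unit[:, 1], unit[:, 0]])
    offset = rng.uniform(-halfwidth, halfwidth, size=n)
    return base + normal * offset[:, None]


def _dist_to_polylines(points, polylines) -> np.ndarray:
    """Min distance from each point to any polyline segment."""
    points = np.asarray(points, dtype=float)
    best = np.full(len(points), np.inf)
    for polyline in polylines:
        pts = np.asarray(polyline, dtype=float)
        for a, b in zip(pts[:-1], pts[1:]):
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0:
                d = np.linalg.norm(points - a, axis=1)
            else:
                t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
                proj = a + t[:, None] * ab
                d = np.linalg.norm(points - proj, axis=1)
            best = np.minimum(best, d)
    return best


def _necrosis_zone(domain: DomainSpec, band: float):
    """Annular 90-degree wedge hugging the first nest's boundary.

    Kept within the peritumoral band so the planted necrotic region is a
    subclass of geometric peritumoral tissue.
    """
    cx, cy, r = domain.nests[0]
    return (cx, cy, r, r + band, -2.0 * np.pi / 3.0, 2.0 * np.pi / 3.0)


def _in_zone(pts: np.ndarray, zone) -> np.ndarray:
    cx, cy, r_in, r_out, a0, a1 = zone
    rel = pts - np.array([cx, cy])
    dist = np.linalg.norm(rel, axis=1)
    angle = np.arctan2(rel[:, 1], rel[:, 0])
    return (dist >= r_in) & (dist <= r_out) & (angle >= a0) & (angle <= a1)


# ---------------------------------------------------------------------------
# tissue generation


def true_gate_config(marker_model: Mapping[str, MarkerParams]) -> GateConfig:
    return GateConfig({m: p.gate_entry() for m, p in marker_model.items()})


def _true_region_labels(
    xy: np.ndarray,
    config: TissueConfig,
    in_necrosis: np.ndarray,
    band: float = 50.0,
    vessel_radius: float = 50.0,
) -> np.ndarray:
    """Geometric ground-truth regions with the assignment precedence."""
    n = len(xy)
    dist_to_nest = np.full(n, np.inf)
    inside_nest = np.zeros(n, dtype=bool)
    for domain in config.domains:
        for cx, cy, r in domain.nests:
            d = np.linalg.norm(xy - np.array([cx, cy]), axis=1)
            inside_nest |= d <= r
            dist_to_nest = np.minimum(dist_to_nest, d - r)
    near_vessel = np.zeros(n, dtype=bool)
    all_vessels = [v for domain in config.domains for v in domain.vessels]
    if all_vessels:
        near_vessel = _dist_to_polylines(xy, all_vessels) <= vessel_radius
    in_band = ~inside_nest & (dist_to_nest <= band)
    labels = np.full(n, "distal", dtype=object)
    labels[in_band] = "peritumoral"
    labels[~inside_nest & near_vessel] = "perivascular"
    labels[in_band & in_necrosis] = "necrotic"
    labels[inside_nest] = "tumor"
    return labels


def generate_tissue(config: TissueConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate one seeded tissue: cell table plus ground truth.

    The returned table has cell_id, x, y, one raw-intensity column per
    marker, and truth columns prefixed ``true_``.  Deterministic for a given
    config and seed (single RNG stream).
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.field_size
    weights = np.array([d.weight for d in config.domains], dtype=float)
    n_per_domain = rng.multinomial(config.n_cells, weights / weights.sum())

    classes, domains_col, xs, ys, debris = [], [], [], [], []
    cc_states = []
    for domain, n_d in zip(config.domains, n_per_domain):
        if n_d == 0:
            continue
        rect = domain.region if domain.region is not None else (0.0, 0.0, w, h)
        x0, y0, x1, y1 = rect
        class_names = ["Tumor"] + list(domain.immune_mix)
        probs = np.array(
            [domain.tumor_fraction]
            + [(1.0 - domain.tumor_fraction) * p for p in domain.immune_mix.values()]
        )
        probs = probs / probs.sum()
        draw = rng.choice(len(class_names), size=n_d, p=probs)
        zone = _necrosis_zone(domain, config.necrosis_band) if domain.necrosis else None

        for i, cls in enumerate(class_names):
            n_c = int((draw == i).sum())
            if n_c == 0:
                continue
            if cls == "Tumor":
                nests = np.asarray(domain.nests, dtype=float)
                nest_w = nests[:, 2] ** 2
                nest_idx = rng.choice(len(nests), size=n_c, p=nest_w / nest_w.sum())
                pts = np.empty((n_c, 2))
                for j in range(len(nests)):
                    sel = nest_idx == j
                    pts[sel] = _point_in_disk(rng, *nests[j], int(sel.sum()))
            elif cls == ENDOTHELIAL_CLASS and domain.vessels:
                vessel_lens = [
                    np.linalg.norm(np.diff(np.asarray(v, float), axis=0), axis=1).sum()
                    for v in domain.vessels
                ]
                vp = np.array(vessel_lens) / np.sum(vessel_lens)
                v_idx = rng.choice(len(domain.vessels), size=n_c, p=vp)
                pts = np.empty((n_c, 2))
                for j, vessel in enumerate(domain.vessels):
                    sel = v_idx == j
                    if sel.any():
                        pts[sel] = _sample_on_polyline(
                            rng, vessel, config.vessel_halfwidth, int(sel.sum())
                        )
            else:
                pts = np.column_stack(
                    [rng.uniform(x0, x1, n_c), rng.uniform(y0, y1, n_c)]
                )
            # necrotic zones hold ~necrosis_thinning of ambient density: cells
            # landing there are mostly relocated outside the zone
            cell_debris = np.zeros(n_c, dtype=bool)
            on_vessel = cls == ENDOTHELIAL_CLASS and domain.vessels
            if zone is not None and cls != "Tumor":
                if not on_vessel:  # vessel cells must stay in their corridor
                    # one keep/relocate decision per cell; relocated cells are
                    # resampled until they land outside the zone
                    stay = rng.random(n_c) <= config.necrosis_thinning
                    pending = _in_zone(pts, zone) & ~stay
                    for _attempt in range(100):
                        n_r = int(pending.sum())
                        if n_r == 0:
                            break
                        pts[pending] = np.column_stack(
                            [rng.uniform(x0, x1, n_r), rng.uniform(y0, y1, n_r)]
                        )
                        pending &= _in_zone(pts, zone)
                cell_debris = _in_zone(pts, zone)
            pts[:, 0] = np.clip(pts[:, 0], 0.0, w)
            pts[:, 1] = np.clip(pts[:, 1], 0.0, h)

            if cls == "Tumor":
                states = rng.choice(
                    list(config.cellcycle_mix),
                    size=n_c,
                    p=list(config.cellcycle_mix.values()),
                )
            else:
                states = np.full(n_c, "none", dtype=object)

            classes.extend([cls] * n_c)
            domains_col.extend([domain.domain_id] * n_c)
            xs.append(pts[:, 0])
            ys.append(pts[:, 1])
            debris.append(cell_debris)
            cc_states.append(states)

    xy = np.column_stack([np.concatenate(xs), np.concatenate(ys)])
    classes = np.array(classes, dtype=object)
    domains_col = np.array(domains_col, dtype=object)
    debris = np.concatenate(debris)
    cc_states = np.concatenate(cc_states)
    n = len(xy)

    # shuffle so row order carries no information
    perm = rng.permutation(n)
    xy, classes, domains_col = xy[perm], classes[perm], domains_col[perm]
    debris, cc_states = debris[perm], cc_states[perm]

    regions = _true_region_labels(xy, config, debris)

    markers = list(config.marker_model)
    positivity = np.zeros((n, len(markers)), dtype=bool)
    class_sig = {c: frozenset(s) for c, s in config.class_signatures.items()}
    for j, marker in enumerate(markers):
        pos = np.array(
            [marker in class_sig.get(c, frozenset()) for c in classes], dtype=bool
        )
        cc_pos = np.array([marker in CELLCYCLE_MARKERS[s] for s in cc_states])
        positivity[:, j] = pos | cc_pos

    intensities = np.empty((n, len(markers)))
    for j, marker in enumerate(markers):
        p = config.marker_model[marker]
        mu = np.where(positivity[:, j], p.pos_mu, p.neg_mu)
        sigma = np.where(positivity[:, j], p.pos_sigma, p.neg_sigma)
        intensities[:, j] = np.exp(rng.normal(mu, sigma))

    table = pd.DataFrame(
        {
            "cell_id": [f"c{i:07d}" for i in range(n)],
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )
    for j, marker in enumerate(markers):
        table[marker] = intensities[:, j]
    table[f"{TRUTH_PREFIX}class"] = classes
    table[f"{TRUTH_PREFIX}state"] = cc_states
    table[f"{TRUTH_PREFIX}region"] = regions
    table[f"{TRUTH_PREFIX}domain"] = domains_col
    table[f"{TRUTH_PREFIX}debris"] = debris

    truth_cells = table[
        ["cell_id"] + [c for c in table.columns if c.startswith(TRUTH_PREFIX)]
    ].copy()
    truth = SyntheticTruth(
        cells=truth_cells,
        positivity=pd.DataFrame(positivity, columns=markers),
        gates=true_gate_config(config.marker_model),
    )
    return table, truth


# ---------------------------------------------------------------------------
# microregion count matrices


@dataclass
class MrSpec:
    """One synthetic microregion: identity, stratum, and latent activities.

    ``activities`` maps gene-set name -> latent activity; genes in that set
    get their negative-binomial mean multiplied by exp(activity * log_fold).
    """

    mr_id: str
    domain: str
    compartment: str
    activities: Mapping[str, float] = dc_field(default_factory=dict)
    enrichment: str = "full"


def generate_mr_counts(
    n_genes: int,
    mr_specs: Sequence[MrSpec],
    gene_sets: Mapping[str, Sequence[str]] | Mapping[str, GeneSet],
    seed: int,
    base_log_mean: float = 3.5,
    base_log_sd: float = 1.0,
    dispersion: float = 0.1,
    log_fold: float = math.log(2.0),
    libsize_sd: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Negative-binomial genes x microregions counts with planted activity.

    Returns (counts, metadata, truth); metadata has mr_id, domain,
    compartment, enrichment columns.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}
    member_idx: dict[str, np.ndarray] = {}
    for name, gs in gene_sets.items():
        members = gs.genes if isinstance(gs, GeneSet) else tuple(gs)
        unknown = [g for g in members if g not in gene_index]
        if unknown:
            raise ConfigurationError(
                f"gene set {name!r} references unknown genes: {unknown[:5]}"
            )
        member_idx[name] = np.array([gene_index[g] for g in members], dtype=int)

    base_mean = np.exp(rng.normal(base_log_mean, base_log_sd, size=n_genes))
    counts = np.empty((n_genes, len(mr_specs)), dtype=int)
    meta_rows = []
    for j, spec in enumerate(mr_specs):
        mean_j = base_mean.copy()
        for set_name, activity in spec.activities.items():
            if set_name not in member_idx:
                raise ConfigurationError(f"unknown gene set {set_name!r} in MrSpec")
            mean_j[member_idx[set_name]] *= math.exp(activity * log_fold)
        mean_j = mean_j * math.exp(rng.normal(0.0, libsize_sd))
        r = 1.0 / dispersion
        p = r / (r + mean_j)
        counts[:, j] = rng.negative_binomial(r, p)
        meta_rows.append(
            {
                "mr_id": spec.mr_id,
                "domain": spec.domain,
                "compartment": spec.compartment,
                "enrichment": spec.enrichment,
            }
        )

    mr_ids = [s.mr_id for s in mr_specs]
    counts_df = pd.DataFrame(counts, index=genes, columns=mr_ids)
    counts_df.index.name = "gene"
    metadata = pd.DataFrame(meta_rows).set_index("mr_id")
    truth_rows = metadata.copy()
    for set_name in member_idx:
        truth_rows[f"activity_{set_name}"] = [
            s.activities.get(set_name, 0.0) for s in mr_specs
        ]
    return counts_df, metadata, SyntheticTruth(microregions=truth_rows)


def plant_correlated_activities(
    set_x: str,
    set_y: str,
    n_tumor: int,
    n_peritumoral: int,
    rho: float = 0.85,
    seed: int = 0,
    activity_sd: float = 1.0,
) -> list[MrSpec]:
    """Microregion specs where two signatures' latent activities correlate
    only in the peritumoral compartment (tumor activities are independent)."""
    if not -1.0 <= rho <= 1.0:
        raise ConfigurationError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    specs = []
    cov = activity_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    peri = rng.multivariate_normal([0.0, 0.0], cov, size=n_peritumoral)
    for i in range(n_tumor):
        a = rng.normal(0.0, activity_sd, size=2)
        specs.append(
            MrSpec(
                mr_id=f"MR_T{i:03d}",
                domain="A",
                compartment="tumor",
                activities={set_x: a[0], set_y: a[1]},
            )
        )
    for i in range(n_peritumoral):
        specs.append(
            MrSpec(
                mr_id=f"MR_P{i:03d}",
                domain="A",
                compartment="peritumoral",
                activities={set_x: peri[i, 0], set_y: peri[i, 1]},
            )
        )
    return specs


def random_gene_sets(
    n_genes: int, set_sizes: Mapping[str, int], seed: int
) -> dict[str, GeneSet]:
    """Disjoint random gene sets drawn from the synthetic gene universe."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    total = sum(set_sizes.values())
    if total > n_genes:
        raise ConfigurationError("gene sets exceed the gene universe")
    chosen = rng.choice(n_genes, size=total, replace=False)
    out, start = {}, 0
    for name, size in set_sizes.items():
        idx = chosen[start:start + size]
        out[name] = GeneSet(name, tuple(genes[i] for i in sorted(idx)))
        start += size
    return out
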