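"""Synthetic inputs with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised without the deposited
laboratory datasets: this module generates (i) co-precipitation experiment
records following the linear sorption isotherm with multiplicative
lognormal noise, (ii) IC-ICP-MS chromatograms as Gaussian peaks over a
drifting baseline, (iii) formation-style tables of banded-iron-formation
sample chemistry drawn within published per-formation ranges, and (iv)
random rooted gene trees containing a monophyletic DPO clade.  All
generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .paleo import BifSample
from .phylo import LabeledTree
from .sorption import SorptionExperiment, ValidationError
from .speciation import Chromatogram, SpeciesWindows, default_windows

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sorption experiments

@dataclass(frozen=True)
class SorptionSimSpec:
    """Co-precipitation experiment series: 0.2 mM Fe(II), 0-28 µM P.

    ``dissolved_grid`` holds the equilibrium dissolved P concentrations (µM)
    at which the isotherm is sampled; the noise-free sorbed-P/sorbed-Fe
    ratio at grid value x is ``true_kads * x``, perturbed multiplicatively
    by lognormal noise with the stated relative sd.  About 99% of the
    initial Fe is reported sorbed, matching near-complete HFO precipitation.
    """

    true_kads: float                      # µM⁻¹
    dissolved_grid: tuple[float, ...] = (0.5, 2.0, 5.0, 10.0, 15.0, 20.0, 28.0)
    fe_initial: float = 200.0             # µM (0.2 mM)
    noise_sd: float = 0.05                # relative (ICP-MS-level scatter)
    replicates: int = 3
    species: str = "PIII"
    matrix: str = "SeaSi"
    ph: float = 6.75
    duration_h: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_kads < 0:
            raise ValidationError(f"true_kads must be >= 0, got {self.true_kads}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.replicates < 1:
            raise ValidationError(f"replicates must be >= 1, got {self.replicates}")
        if any(x < 0 for x in self.dissolved_grid):
            raise ValidationError("dissolved_grid values must be >= 0")
        if self.fe_initial <= 0:
            raise ValidationError(f"fe_initial must be > 0, got {self.fe_initial}")


FE_SORBED_FRACTION = 0.99


def gen_sorption_dataset(spec: SorptionSimSpec) -> list[SorptionExperiment]:
    """One experiment record per grid value and replicate.

    Records are built backwards from the isotherm so that the measurement
    chain (dilution un-scaling, mass balance) recovers the model exactly:
    sorbed Fe is 99% of the initial load, sorbed P is the (noisy) ratio
    times sorbed Fe, the initial P load is dissolved + sorbed, and measured
    aliquot concentrations are the in-vessel values over a pH-titration
    dilution factor.
    """
    rng = np.random.default_rng(spec.seed)
    fe_sorbed = FE_SORBED_FRACTION * spec.fe_initial
    fe_final = spec.fe_initial - fe_sorbed
    out = []
    for rep in range(spec.replicates):
        for x in spec.dissolved_grid:
            ratio = spec.true_kads * x
            if spec.noise_sd > 0:
                # lognormal with unit median keeps simulated ratios non-negative
                ratio *= rng.lognormal(mean=0.0, sigma=spec.noise_sd)
            sorbed_p = ratio * fe_sorbed
            dilution = 1.0 + 0.1 * rng.random()   # NaOH/HCl additions, up to 10%
            out.append(
                SorptionExperiment(
                    species=spec.species,
                    matrix=spec.matrix,
                    ph=spec.ph,
                    duration_h=spec.duration_h,
                    p_initial=x + sorbed_p,
                    p_final_dissolved=x / dilution,
                    fe_initial=spec.fe_initial,
                    fe_final_dissolved=fe_final / dilution,
                    dilution_factor=dilution,
                    replicate_id=rep,
                )
            )
    return out


# ---------------------------------------------------------------------------
# chromatograms

@dataclass(frozen=True)
class SpeciesPeak:
    name: str
    retention_time: float       # s
    true_concentration: float   # ppb in the extract
    response_factor: float      # peak area (intensity*s) per ppb


@dataclass(frozen=True)
class ChromSimSpec:
    """Gaussian peaks over a linearly drifting baseline with white noise.

    Each species occupies its own 3-minute window (1 min pre-peak
    background, 1 min peak, 1 min post-peak background); peak amplitude is
    set so that the integrated area equals response_factor x concentration.
    """

    species: tuple[SpeciesPeak, ...]
    peak_sigma: float = 5.0             # s
    baseline_level: float = 50.0        # intensity counts
    drift_slope: float = 0.0            # counts per s
    noise_sd: float = 0.0               # counts
    sampling_interval: float = 1.0      # s
    seed: int = 0

    def __post_init__(self) -> None:
        rts = [s.retention_time for s in self.species]
        if len(set(rts)) != len(rts):
            raise ValidationError("retention times must be distinct")
        if self.peak_sigma <= 0:
            raise ValidationError(f"peak_sigma must be > 0, got {self.peak_sigma}")
        if self.sampling_interval <= 0:
            raise ValidationError(f"sampling_interval must be > 0, got {self.sampling_interval}")


def gen_chromatogram(spec: ChromSimSpec, sample_id: str = "synthetic") -> Chromatogram:
    """Simulate one trace covering every species' 3-minute window."""
    rts = sorted(s.retention_time for s in spec.species)
    for a, b in zip(rts, rts[1:]):
        if b - a < 6 * spec.peak_sigma:
            logger.warning(
                "peaks at %.1f s and %.1f s are closer than 6*sigma=%.1f s; "
                "integration windows may overlap", a, b, 6 * spec.peak_sigma,
            )
    t0 = min(rts) - 90.0 if rts else 0.0
    t1 = max(rts) + 90.0 if rts else 180.0
    time = np.arange(t0, t1 + spec.sampling_interval / 2, spec.sampling_interval)
    rng = np.random.default_rng(spec.seed)
    signal = spec.baseline_level + spec.drift_slope * (time - time[0])
    for sp in spec.species:
        area = sp.response_factor * sp.true_concentration
        amplitude = area / (spec.peak_sigma * math.sqrt(2.0 * math.pi))
        signal = signal + amplitude * np.exp(-0.5 * ((time - sp.retention_time) / spec.peak_sigma) ** 2)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=time.size)
    windows = {sp.name: default_windows(sp.retention_time) for sp in spec.species}
    return Chromatogram(sample_id=sample_id, time=time, intensity=signal, species_windows=windows)


# ---------------------------------------------------------------------------
# BIF sample tables

@dataclass(frozen=True)
class BifSimSpec:
    """Formation-style table: uniform draws within per-quantity ranges.

    Default ranges follow the published Kuruman-Gamohaan values (extract
    phosphite 0.22-0.37 ppm, extract phosphate 1.59-28.4 ppm, bulk total P
    70-950 ppm, bulk Fe 26.8-44.8 wt%).  Extract phosphite is redrawn below
    extract phosphate, as observed in every measured sample.
    """

    n_samples: int = 7
    formation: str = "Kuruman-Gamohaan"
    p3_range: tuple[float, float] = (0.22, 0.37)      # ppm rock, extract phosphite
    p5_range: tuple[float, float] = (1.59, 28.4)      # ppm rock, extract phosphate
    pp_range: tuple[float, float] = (0.0, 0.5)        # ppm rock, extract pyrophosphate
    total_p_range: tuple[float, float] = (70.0, 950.0)  # ppm bulk
    fe_range: tuple[float, float] = (26.8, 44.8)        # wt% bulk
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p3_range", "p5_range", "pp_range", "total_p_range", "fe_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValidationError(f"{name} must satisfy 0 <= min <= max, got {(lo, hi)}")
        if self.fe_range[1] > 70:
            raise ValidationError(f"Fe must be <= 70 wt%, got max {self.fe_range[1]}")
        if self.n_samples < 1:
            raise ValidationError(f"n_samples must be >= 1, got {self.n_samples}")


def gen_bif_table(spec: BifSimSpec) -> list[BifSample]:
    """Draw ``n_samples`` records uniformly within the stated ranges.

    The invariant extract-P(III) < extract-P(V) holds for every record; a
    draw violating it (possible only when the ranges overlap) is resampled.
    """
    rng = np.random.default_rng(spec.seed)
    degenerate = (
        spec.p3_range[0] == spec.p3_range[1] and spec.p5_range[0] == spec.p5_range[1]
    )
    out = []
    for i in range(spec.n_samples):
        p3 = rng.uniform(*spec.p3_range)
        p5 = rng.uniform(*spec.p5_range)
        while p3 >= p5 and not degenerate:
            p3 = rng.uniform(*spec.p3_range)
            p5 = rng.uniform(*spec.p5_range)
        pp = rng.uniform(*spec.pp_range)
        total_p = rng.uniform(*spec.total_p_range)
        total_p = max(total_p, p3 + p5 + pp)  # bulk must hold at least the extract
        fe = rng.uniform(*spec.fe_range)
        out.append(
            BifSample(
                sample_id=f"{spec.formation}-{i + 1:02d}",
                formation=spec.formation,
                extract_p3=p3,
                extract_p5=p5,
                extract_pp=pp,
                total_p=total_p,
                total_fe=fe,
            )
        )
    return out


#: Per-formation simulation specs mirroring the published summary table
#: (extract phosphite/phosphate, bulk total P, bulk Fe ranges; sample counts).
FORMATION_SPECS: dict[str, BifSimSpec] = {
    "Kuruman-Gamohaan": BifSimSpec(
        n_samples=7, formation="Kuruman-Gamohaan",
        p3_range=(0.22, 0.37), p5_range=(1.59, 28.4),
        total_p_range=(70.0, 950.0), fe_range=(26.8, 44.8),
    ),
    "Joffre": BifSimSpec(
        n_samples=4, formation="Joffre",
        p3_range=(0.02, 0.05), p5_range=(2.21, 15.4),
        total_p_range=(20.0, 110.0), fe_range=(27.4, 34.7),
    ),
    "Dales Gorge": BifSimSpec(
        n_samples=6, formation="Dales Gorge",
        p3_range=(0.15, 0.56), p5_range=(1.59, 60.6),
        total_p_range=(20.0, 3720.0), fe_range=(29.6, 55.0),
    ),
    "Marra Mamba": BifSimSpec(
        n_samples=4, formation="Marra Mamba",
        p3_range=(0.23, 0.34), p5_range=(3.32, 11.6),
        total_p_range=(160.0, 1090.0), fe_range=(30.4, 55.0),
    ),
}


def gen_formation_suite(seed: int = 0) -> list[BifSample]:
    """Samples for all four formations, seeds derived per formation."""
    out = []
    for k, (name, spec) in enumerate(sorted(FORMATION_SPECS.items())):
        s = BifSimSpec(**{**vars(spec), "seed": (seed * 1000 + k) % (2**31)})
        out.extend(gen_bif_table(s))
    return out


# ---------------------------------------------------------------------------
# labeled trees

@dataclass(frozen=True)
class TreeSimSpec:
    """Random rooted binary tree with a monophyletic DPO clade."""

    n_tips: int = 12
    dpo_clade_size: int = 4
    branch_length_scale: float = 0.1   # substitutions/site, exponential mean
    require_both_states: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValidationError(f"n_tips must be >= 2, got {self.n_tips}")
        if not (0 <= self.dpo_clade_size <= self.n_tips):
            raise ValidationError(
                f"dpo_clade_size must be in [0, {self.n_tips}], got {self.dpo_clade_size}"
            )
        if self.branch_length_scale <= 0:
            raise ValidationError(f"branch_length_scale must be > 0, got {self.branch_length_scale}")
        if self.require_both_states and self.dpo_clade_size in (0, self.n_tips):
            raise ValidationError("both states required but dpo_clade_size leaves a single state")


def _random_topology(labels: Sequence[str], rng: np.random.Generator,
                     taxa: dendropy.TaxonNamespace) -> dendropy.Tree:
    """Rooted binary topology by random sequential attachment."""
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    first = tree.seed_node.new_child()
    first.taxon = taxa.require_taxon(label=labels[0])
    if len(labels) > 1:
        second = tree.seed_node.new_child()
        second.taxon = taxa.require_taxon(label=labels[1])
    for label in labels[2:]:
        edges = [e for e in tree.preorder_edge_iter() if e.tail_node is not None]
        target = edges[rng.integers(len(edges))]
        # bisect the target edge and hang the new tip off the midpoint node
        tail, head = target.tail_node, target.head_node
        tail.remove_child(head)
        mid = tail.new_child()
        mid.add_child(head)
        tip = mid.new_child()
        tip.taxon = taxa.require_taxon(label=label)
    return tree


def gen_labeled_tree(spec: TreeSimSpec) -> LabeledTree:
    """Random rooted binary tree: DPO tips form one clade, the rest are APO.

    The DPO clade is grown from a single placeholder tip of an APO backbone
    tree, so monophyly (and, for 0 < clade size < n_tips, a root outside
    the clade) holds by construction.  Branch lengths are exponential with
    the given scale.
    """
    rng = np.random.default_rng(spec.seed)
    k, n = spec.dpo_clade_size, spec.n_tips
    apo_labels = [f"apo{i + 1}" for i in range(n - k)]
    dpo_labels = [f"dpo{i + 1}" for i in range(k)]
    taxa = dendropy.TaxonNamespace()

    if k == 0:
        tree = _random_topology(apo_labels, rng, taxa)
    elif k == n:
        tree = _random_topology(dpo_labels, rng, taxa)
    elif k == 1:
        tree = _random_topology(apo_labels + dpo_labels, rng, taxa)
    else:
        backbone = _random_topology(apo_labels + ["__dpo_anchor__"], rng, taxa)
        clade = _random_topology(dpo_labels, rng, taxa)
        anchor = next(
            leaf for leaf in backbone.leaf_node_iter()
            if leaf.taxon.label == "__dpo_anchor__"
        )
        anchor.taxon = None
        for child in clade.seed_node.child_nodes():
            clade.seed_node.remove_child(child)
            anchor.add_child(child)
        taxa.remove_taxon_label("__dpo_anchor__")
        tree = backbone
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length = float(rng.exponential(spec.branch_length_scale))
    tree.is_rooted = True
    states = {lbl: "APO" for lbl in apo_labels} | {lbl: "DPO" for lbl in dpo_labels}
    return LabeledTree(tree=tree, tip_states=states, rooted=True)
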