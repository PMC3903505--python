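"""Forward simulator of a DNA-SIP experiment.

The chain being emulated, for a gut-microbiota labeling experiment with a
13C substrate:

1. a bacterial community with per-taxon GC content and relative abundance,
   plus co-extracted unlabeled host DNA and a low uniform background of
   nonspecific DNA;
2. labeling: during the feeding window each taxon replaces a fraction
   (its *turnover*) of its DNA with newly synthesized DNA whose 13C atom
   fraction reflects how much of its carbon came from the labeled substrate
   (*assimilation*);
3. isopycnic banding in a CsCl gradient: each DNA pool bands as a Gaussian
   around its buoyant density, BD = 1.660 + 0.098*GC for unlabeled DNA plus
   up to +0.036 g/ml at full 13C labeling (values from the standard SIP
   protocol literature; all config-exposed);
4. fractionation from the bottom (fraction 1, densest) into equal fractions
   and DNA quantification per fraction;
5. amplicon sequencing of each fraction (multinomial reads over the
   *microbial* DNA in that fraction — host DNA is present in the gradient but
   invisible to 16S primers), in replicate;
6. bulk isotope-ratio mass spectrometry (IRMS) of the total extract.

Every stochastic stage draws from a substream derived from one top-level seed
and a stable per-stage tag, so adding a stage never perturbs earlier ones.
Ground truth (who was labeled, where their DNA bands) is recorded so recovery
tests can join inference output back to the simulation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import isotope
from .containers import CountTable, LINEAGE_RANKS, make_sample_id
from .gradient import FractionRecord, FractionSet

__all__ = [
    "Taxon",
    "CommunityProfile",
    "LabelingScenario",
    "DnaPool",
    "LabeledCommunity",
    "GradientConfig",
    "NATURAL_DELTA_C13",
    "natural_atom_fraction",
    "generate_community",
    "apply_labeling",
    "pool_buoyant_density",
    "run_gradient",
    "monte_carlo_gradient",
    "sample_reads",
    "simulate_irms",
    "build_truth",
    "write_truth",
    "read_truth",
    "simulate_experiment",
]

#: Natural delta13C of unlabeled DNA (permil vs VPDB), the control baseline.
NATURAL_DELTA_C13 = -30.7

_PHYLA = ("Firmicutes", "Proteobacteria", "Actinobacteria", "Bacteroidetes", "Acidobacteria")


def natural_atom_fraction(baseline_delta: float = NATURAL_DELTA_C13) -> float:
    """13C atom fraction of unlabeled biomass at the control baseline delta."""
    return isotope.atom_fraction_from_delta(baseline_delta)


def substream(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG derived from one top-level seed."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(stage.encode()) % 2**31])


# ---------------------------------------------------------------------------
# community and labeling state


@dataclass(frozen=True)
class Taxon:
    id: str
    gc: float
    base_abundance: float
    lineage: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"gc must be in [0, 1], got {self.gc} for {self.id}")
        if self.base_abundance < 0:
            raise ValueError(f"abundance must be >= 0 for {self.id}")


@dataclass
class CommunityProfile:
    """A bacterial community plus the non-amplicon DNA context it sits in.

    ``host_dna_fraction`` is the share of total extracted DNA that is
    host-derived (co-extracted gut tissue); ``background_fraction`` is the
    share spread uniformly over all gradient fractions (nonspecific carryover,
    observed in every SIP gradient). The remainder is bacterial community DNA,
    divided among taxa by ``base_abundance``.
    """

    taxa: list[Taxon]
    host_dna_fraction: float = 0.5
    background_fraction: float = 0.05
    host_gc: float = 0.37  # lepidopteran genomic GC

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("community needs at least one taxon")
        ids = [t.id for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ValueError("taxon ids must be unique")
        total = sum(t.base_abundance for t in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"base abundances must sum to 1, got {total}")
        if not 0.0 <= self.host_dna_fraction < 1.0:
            raise ValueError("host_dna_fraction must be in [0, 1)")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must be in [0, 1)")
        if self.host_dna_fraction + self.background_fraction >= 1.0:
            raise ValueError("host + background DNA must leave room for the community")

    @property
    def community_fraction(self) -> float:
        return 1.0 - self.host_dna_fraction - self.background_fraction

    def abundances(self) -> pd.Series:
        return pd.Series({t.id: t.base_abundance for t in self.taxa})

    def lineage_frame(self) -> pd.DataFrame:
        rows = {t.id: {r: t.lineage.get(r, "") for r in LINEAGE_RANKS} for t in self.taxa}
        return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class LabelingScenario:
    """What the feeding window did to each taxon's DNA.

    ``turnover`` — fraction of a taxon's DNA newly synthesized during
    labeling; ``assimilation`` — fraction of carbon in that new DNA drawn from
    the labeled substrate. Either can be a single number applied to all taxa
    or a per-taxon mapping (missing taxa default to 0 turnover / the scalar
    assimilation).
    """

    substrate_af: float = 0.99
    duration_label: str = ""
    turnover: float | Mapping[str, float] = 0.0
    assimilation: float | Mapping[str, float] = 1.0

    def __post_init__(self) -> None:
        def _check(name: str, v) -> None:
            vals = v.values() if isinstance(v, Mapping) else [v]
            for x in vals:
                if not 0.0 <= x <= 1.0:
                    raise ValueError(f"{name} values must be in [0, 1], got {x}")

        _check("substrate_af", self.substrate_af)
        _check("turnover", self.turnover)
        _check("assimilation", self.assimilation)

    def turnover_of(self, taxon_id: str) -> float:
        if isinstance(self.turnover, Mapping):
            return float(self.turnover.get(taxon_id, 0.0))
        return float(self.turnover)

    def assimilation_of(self, taxon_id: str) -> float:
        if isinstance(self.assimilation, Mapping):
            return float(self.assimilation.get(taxon_id, 1.0))
        return float(self.assimilation)


@dataclass(frozen=True)
class DnaPool:
    """A mass of DNA with a single GC content and 13C atom fraction."""

    mass: float
    af: float
    gc: float

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("pool mass must be >= 0")
        if not 0.0 <= self.af <= 1.0:
            raise ValueError("atom fraction must be in [0, 1]")


@dataclass
class LabeledCommunity:
    """Post-labeling DNA pools, masses normalized to a total extract of 1.

    Each taxon carries an old (natural-abundance) and a new (labeled) pool;
    the host pool is unlabeled; the background pool is spread uniformly over
    the gradient and is compositionally a miniature of the community (it is
    bacterial DNA, so it amplifies).
    """

    pools: dict[str, tuple[DnaPool, ...]]
    host_pool: DnaPool
    background_mass: float
    natural_af: float
    community: CommunityProfile

    def total_mass(self) -> float:
        taxa = sum(p.mass for ps in self.pools.values() for p in ps)
        return taxa + self.host_pool.mass + self.background_mass


# ---------------------------------------------------------------------------
# gradient configuration


@dataclass(frozen=True)
class GradientConfig:
    """Geometry and physics of the simulated CsCl gradient.

    Densities in g/ml. Fraction 1 is the bottom (densest); the ``n_fractions``
    fraction centers fall linearly from ``bd_bottom`` to ``bd_top``.
    ``band_sigma`` is the Gaussian banding width of a homogeneous DNA pool;
    ``host_band_sigma`` is wider because sheared host genomic DNA is
    heterogeneous in GC across fragments. ``bd_intercept``/``gc_slope`` encode
    BD = 1.660 + 0.098*GC, and ``full_label_shift`` the +0.036 g/ml at full
    13C substitution.
    """

    n_fractions: int = 12
    bd_bottom: float = 1.761
    bd_top: float = 1.688
    band_sigma: float = 0.003
    host_band_sigma: float = 0.008
    mean_bd: float = 1.725  # informational: density of the starting solution
    bd_intercept: float = 1.660
    gc_slope: float = 0.098
    full_label_shift: float = 0.036
    total_dna_ng: float = 1500.0
    volume_ul: float = 425.0

    def __post_init__(self) -> None:
        if self.n_fractions < 3:
            raise ValueError("need at least 3 fractions")
        if not self.bd_bottom > self.bd_top:
            raise ValueError("bd_bottom must exceed bd_top")
        if not self.band_sigma > 0:
            raise ValueError("band_sigma must be positive")

    def fraction_densities(self) -> np.ndarray:
        return np.linspace(self.bd_bottom, self.bd_top, self.n_fractions)

    def window_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(upper, lower) density bounds per fraction; outermost are open."""
        c = self.fraction_densities()
        inner = (c[:-1] + c[1:]) / 2.0
        upper = np.concatenate([[np.inf], inner])
        lower = np.concatenate([inner, [-np.inf]])
        return upper, lower


# ---------------------------------------------------------------------------
# operations


def generate_community(
    n_taxa: int,
    abundance_model: str = "lognormal",
    gc_bounds: tuple[float, float] = (0.30, 0.70),
    host_dna_fraction: float = 0.5,
    background_fraction: float = 0.05,
    seed: int = 0,
    lognormal_sigma: float = 1.0,
) -> CommunityProfile:
    """Draw a random community profile.

    ``abundance_model`` is ``"uniform"`` (equal abundances) or ``"lognormal"``
    (log-normal with the given log-space sigma, then closed to sum to 1 —
    the usual shape of amplicon communities: a few dominants, a long tail).
    GC contents are uniform on ``gc_bounds``. Reproducible for a fixed seed.
    """
    if n_taxa < 1:
        raise ValueError(f"n_taxa must be >= 1, got {n_taxa}")
    lo, hi = gc_bounds
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"gc_bounds must be ordered within [0, 1], got {gc_bounds}")
    rng = substream(seed, "community")
    if abundance_model == "uniform":
        raw = np.ones(n_taxa)
    elif abundance_model == "lognormal":
        raw = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n_taxa)
    else:
        raise ValueError(f"unknown abundance_model {abundance_model!r}")
    abund = raw / raw.sum()
    gcs = rng.uniform(lo, hi, size=n_taxa)
    width = len(str(n_taxa))
    taxa = [
        Taxon(
            id=f"otu{i + 1:0{width}d}",
            gc=float(gcs[i]),
            base_abundance=float(abund[i]),
            lineage={
                "phylum": _PHYLA[i % len(_PHYLA)],
                "family": f"Family{i % 7 + 1}",
                "genus": f"Genus{i + 1:0{width}d}",
            },
        )
        for i in range(n_taxa)
    ]
    return CommunityProfile(
        taxa=taxa,
        host_dna_fraction=host_dna_fraction,
        background_fraction=background_fraction,
    )


def apply_labeling(
    community: CommunityProfile,
    scenario: LabelingScenario,
    natural_af: float | None = None,
) -> LabeledCommunity:
    """Split each taxon's DNA into an old (natural) and a new (labeled) pool.

    The new pool carries mass proportional to the taxon's turnover and an atom
    fraction ``natural + assimilation * (substrate - natural)``. Total DNA
    mass is conserved (new DNA replaces old; growth factor 1). Host and
    background DNA stay at natural abundance.
    """
    if natural_af is None:
        natural_af = natural_atom_fraction()
    if not 0.0 < natural_af < 0.02:
        raise ValueError(f"natural_af should be a natural-abundance value, got {natural_af}")
    comm_mass = community.community_fraction
    pools: dict[str, tuple[DnaPool, ...]] = {}
    for t in community.taxa:
        mass = t.base_abundance * comm_mass
        turn = scenario.turnover_of(t.id)
        assim = scenario.assimilation_of(t.id)
        new_af = natural_af + assim * (scenario.substrate_af - natural_af)
        taxon_pools = []
        if 1.0 - turn > 0:
            taxon_pools.append(DnaPool(mass=mass * (1.0 - turn), af=natural_af, gc=t.gc))
        if turn > 0:
            taxon_pools.append(DnaPool(mass=mass * turn, af=new_af, gc=t.gc))
        pools[t.id] = tuple(taxon_pools)
    host = DnaPool(mass=community.host_dna_fraction, af=natural_af, gc=community.host_gc)
    return LabeledCommunity(
        pools=pools,
        host_pool=host,
        background_mass=community.background_fraction,
        natural_af=natural_af,
        community=community,
    )


def pool_buoyant_density(
    gc: float,
    af: float,
    natural_af: float | None = None,
    config: GradientConfig | None = None,
) -> float:
    """Buoyant density of a DNA pool from its GC content and 13C atom fraction.

    BD = intercept + slope*GC + full_label_shift * (af - natural)/(1 - natural).
    """
    if config is None:
        config = GradientConfig()
    if natural_af is None:
        natural_af = natural_atom_fraction()
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    if not 0.0 <= af <= 1.0:
        raise ValueError("af must be in [0, 1]")
    label_term = config.full_label_shift * (af - natural_af) / (1.0 - natural_af)
    return config.bd_intercept + config.gc_slope * gc + label_term


def _band_over_windows(bd: np.ndarray, sigma: np.ndarray, config: GradientConfig) -> np.ndarray:
    """Gaussian band mass share per fraction window; rows = pools, cols = fractions."""
    upper, lower = config.window_edges()
    bd = np.asarray(bd, float)[:, None]
    sigma = np.asarray(sigma, float)[:, None]
    hi = np.where(np.isinf(upper), 1.0, ndtr((upper[None, :] - bd) / sigma))
    lo = np.where(np.isinf(lower), 0.0, ndtr((lower[None, :] - bd) / sigma))
    return hi - lo


HOST_ROW = "__host__"


def run_gradient(
    labeled: LabeledCommunity, config: GradientConfig | None = None
) -> tuple[FractionSet, pd.DataFrame]:
    """Band every DNA pool over the fraction windows.

    Returns the per-fraction DNA profile as a :class:`FractionSet` (total DNA,
    host included, scaled to ``config.total_dna_ng``) and the taxon x fraction
    relative-mass matrix (host as the ``__host__`` row; each taxon row already
    includes its share of the uniform background). Mass is conserved exactly
    because the outermost windows are open-ended.
    """
    if config is None:
        config = GradientConfig()
    if not labeled.pools:
        raise ValueError("empty community")
    taxa = list(labeled.pools)
    n = config.n_fractions

    bds, sigmas, masses, owners = [], [], [], []
    for tid in taxa:
        for p in labeled.pools[tid]:
            bds.append(pool_buoyant_density(p.gc, p.af, labeled.natural_af, config))
            sigmas.append(config.band_sigma)
            masses.append(p.mass)
            owners.append(tid)
    bds.append(pool_buoyant_density(labeled.host_pool.gc, labeled.host_pool.af,
                                    labeled.natural_af, config))
    sigmas.append(config.host_band_sigma)
    masses.append(labeled.host_pool.mass)
    owners.append(HOST_ROW)

    shares = _band_over_windows(np.array(bds), np.array(sigmas), config)
    banded = shares * np.array(masses)[:, None]

    matrix = pd.DataFrame(0.0, index=taxa + [HOST_ROW], columns=np.arange(1, n + 1))
    for row, owner in zip(banded, owners):
        matrix.loc[owner] += row
    # uniform background, apportioned to taxa by base abundance
    abund = labeled.community.abundances()
    bg_per_fraction = labeled.background_mass / n
    matrix.loc[taxa] += np.outer(abund[taxa].to_numpy(), np.full(n, bg_per_fraction))

    totals = matrix.sum(axis=0).to_numpy()
    densities = config.fraction_densities()
    fs = FractionSet(
        fractions=[
            FractionRecord(
                index=i + 1,
                volume_ul=config.volume_ul,
                density=float(densities[i]),
                dna_ng=float(totals[i] * config.total_dna_ng / labeled.total_mass()),
            )
            for i in range(n)
        ],
        sample="simulated",
    )
    return fs, matrix


def monte_carlo_gradient(
    labeled: LabeledCommunity,
    config: GradientConfig | None = None,
    n_molecules: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Molecule-level brute-force banding: per-fraction share of total DNA.

    Draws individual molecules from the DNA pools in proportion to mass,
    perturbs each molecule's density by its pool's Gaussian band width, and
    assigns it to the fraction whose density window contains it (background
    molecules land in a uniformly random fraction). Serves as an independent
    cross-check of :func:`run_gradient`.
    """
    if config is None:
        config = GradientConfig()
    rng = substream(seed, "mc-gradient")
    bds, sigmas, masses = [], [], []
    for ps in labeled.pools.values():
        for p in ps:
            bds.append(pool_buoyant_density(p.gc, p.af, labeled.natural_af, config))
            sigmas.append(config.band_sigma)
            masses.append(p.mass)
    bds.append(pool_buoyant_density(labeled.host_pool.gc, labeled.host_pool.af,
                                    labeled.natural_af, config))
    sigmas.append(config.host_band_sigma)
    masses.append(labeled.host_pool.mass)

    masses = np.array(masses + [labeled.background_mass])
    probs = masses / masses.sum()
    n_pools = len(bds)
    choice = rng.choice(n_pools + 1, size=n_molecules, p=probs)
    counts = np.zeros(config.n_fractions)

    n_bg = int(np.sum(choice == n_pools))
    if n_bg:
        frac = rng.integers(0, config.n_fractions, size=n_bg)
        np.add.at(counts, frac, 1)

    upper, _ = config.window_edges()
    # density decreases with index: molecule falls in the first window whose
    # lower edge it exceeds
    inner_edges = upper[1:]  # finite edges, decreasing
    for k in range(n_pools):
        n_k = int(np.sum(choice == k))
        if not n_k:
            continue
        dens = rng.normal(bds[k], sigmas[k], size=n_k)
        idx = np.searchsorted(-inner_edges, -dens, side="right")
        np.add.at(counts, idx, 1)
    return counts / n_molecules


def sample_reads(
    mass_matrix: pd.DataFrame,
    depth: int,
    n_replicates: int = 3,
    replicate_noise: float = 0.0,
    seed: int = 0,
    condition: str = "labeled",
    lineages: pd.DataFrame | None = None,
) -> CountTable:
    """Multinomial amplicon sampling of each gradient fraction.

    Host DNA (the ``__host__`` row) is excluded before proportions are formed:
    16S primers do not amplify host DNA. With ``replicate_noise > 0`` the
    per-replicate proportions are Dirichlet-perturbed around the fraction's
    mass proportions (concentration = proportions / replicate_noise), giving
    overdispersed biological triplicates; at 0 the draws are pure multinomial.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    mat = mass_matrix.drop(index=[HOST_ROW], errors="ignore")
    taxa = list(mat.index)
    rng = substream(seed, f"reads-{condition}")
    cols: dict[str, np.ndarray] = {}
    rows = []
    for frac in mat.columns:
        masses = mat[frac].to_numpy(dtype=float)
        total = masses.sum()
        if not total > 0:
            raise ValueError(f"fraction {frac} has no amplifiable DNA")
        p = masses / total
        for rep in range(1, n_replicates + 1):
            p_rep = p
            if replicate_noise > 0:
                alpha = np.clip(p / replicate_noise, 1e-12, None)
                p_rep = rng.dirichlet(alpha)
            counts = rng.multinomial(depth, p_rep)
            sid = make_sample_id(condition, int(frac), rep)
            cols[sid] = counts
            rows.append({"sample_id": sid, "condition": condition,
                         "fraction": int(frac), "bin": pd.NA, "replicate": rep})
    counts_df = pd.DataFrame(cols, index=taxa)
    samples = pd.DataFrame(rows).set_index("sample_id")
    return CountTable(counts=counts_df, samples=samples, lineages=lineages)


def simulate_irms(
    labeled: LabeledCommunity,
    baseline_delta: float = NATURAL_DELTA_C13,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> isotope.IsotopeMeasurement:
    """Bulk delta13C of the total extract (host and background included).

    The bulk atom fraction is the mass-weighted mean over all DNA pools,
    anchored so that an all-natural community reads exactly
    ``baseline_delta``; Gaussian measurement noise (permil) is added on the
    delta scale.
    """
    pools = [p for ps in labeled.pools.values() for p in ps]
    pools.append(labeled.host_pool)
    masses = np.array([p.mass for p in pools] + [labeled.background_mass])
    afs = np.array([p.af for p in pools] + [labeled.natural_af])
    bulk_af = float(np.average(afs, weights=masses))
    # anchor: express the bulk as natural baseline + excess
    baseline_af = isotope.atom_fraction_from_delta(baseline_delta)
    delta = isotope.delta_from_atom_fraction(baseline_af + (bulk_af - labeled.natural_af))
    if noise_sd > 0:
        delta += float(substream(seed, "irms").normal(0.0, noise_sd))
    return isotope.IsotopeMeasurement.from_delta(delta, sd=noise_sd or None)


# ---------------------------------------------------------------------------
# ground truth

TRUTH_SCHEMA = "pyrosip-truth/1"


def build_truth(
    community: CommunityProfile,
    scenario: LabelingScenario,
    config: GradientConfig | None = None,
) -> dict:
    """Per-taxon ground truth (turnover, pool atom fractions, BDs) as a dict.

    The documented schema: top-level keys ``schema``, ``host``,
    ``background_fraction``, ``scenario`` and ``taxa`` (a list with keys
    ``id``, ``gc``, ``base_abundance``, ``lineage``, ``turnover``,
    ``assimilation``, ``new_pool_af``, ``bd_unlabeled``, ``bd_labeled``,
    ``labeled`` — the truly-labeled flag is turnover > 0 and new-pool
    enrichment above natural abundance).
    """
    if config is None:
        config = GradientConfig()
    nat = natural_atom_fraction()
    taxa = []
    for t in community.taxa:
        turn = scenario.turnover_of(t.id)
        assim = scenario.assimilation_of(t.id)
        new_af = nat + assim * (scenario.substrate_af - nat)
        taxa.append(
            {
                "id": t.id,
                "gc": t.gc,
                "base_abundance": t.base_abundance,
                "lineage": dict(t.lineage),
                "turnover": turn,
                "assimilation": assim,
                "new_pool_af": new_af,
                "bd_unlabeled": pool_buoyant_density(t.gc, nat, nat, config),
                "bd_labeled": pool_buoyant_density(t.gc, new_af, nat, config),
                "labeled": bool(turn > 0 and new_af > nat),
            }
        )
    doc = {
        "schema": TRUTH_SCHEMA,
        "host": {"dna_fraction": community.host_dna_fraction, "gc": community.host_gc},
        "background_fraction": community.background_fraction,
        "scenario": {
            "substrate_af": scenario.substrate_af,
            "duration_label": scenario.duration_label,
            "turnover": scenario.turnover if not isinstance(scenario.turnover, Mapping)
            else dict(scenario.turnover),
            "assimilation": scenario.assimilation
            if not isinstance(scenario.assimilation, Mapping)
            else dict(scenario.assimilation),
        },
        "taxa": taxa,
    }
    return doc


def write_truth(
    community: CommunityProfile,
    scenario: LabelingScenario,
    path: str | Path,
    config: GradientConfig | None = None,
) -> dict:
    """Write the :func:`build_truth` document to ``path`` as JSON."""
    doc = build_truth(community, scenario, config)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
    return doc


def read_truth(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != TRUTH_SCHEMA:
        raise ValueError(f"not a truth file (schema {doc.get('schema')!r})")
    return doc


# ---------------------------------------------------------------------------
# one-call experiment


@dataclass
class ExperimentResult:
    """Everything one simulated SIP experiment produces."""

    control_fractions: FractionSet
    labeled_fractions: FractionSet
    control_mass: pd.DataFrame
    labeled_mass: pd.DataFrame
    counts: CountTable  # both conditions, per fraction
    truth: dict
    bulk_delta_labeled: float
    bulk_delta_control: float


def simulate_experiment(
    community: CommunityProfile,
    scenario: LabelingScenario,
    config: GradientConfig | None = None,
    depth: int = 5000,
    n_replicates: int = 3,
    replicate_noise: float = 0.0,
    irms_noise_sd: float = 0.0,
    seed: int = 0,
) -> ExperimentResult:
    """Run the labeled arm and an unlabeled control through the whole chain."""
    if config is None:
        config = GradientConfig()
    control_scenario = LabelingScenario(
        substrate_af=scenario.substrate_af, duration_label="control", turnover=0.0
    )
    lab = apply_labeling(community, scenario)
    ctl = apply_labeling(community, control_scenario)
    fs_lab, m_lab = run_gradient(lab, config)
    fs_ctl, m_ctl = run_gradient(ctl, config)
    fs_lab.condition, fs_lab.sample = "labeled", "labeled"
    fs_ctl.condition, fs_ctl.sample = "control", "control"
    lineages = community.lineage_frame()
    ct_lab = sample_reads(m_lab, depth, n_replicates, replicate_noise, seed,
                          condition="labeled", lineages=lineages)
    ct_ctl = sample_reads(m_ctl, depth, n_replicates, replicate_noise, seed,
                          condition="control", lineages=lineages)
    from .containers import concat_tables

    counts = concat_tables([ct_lab, ct_ctl])
    truth = build_truth(community, scenario, config)
    return ExperimentResult(
        control_fractions=fs_ctl,
        labeled_fractions=fs_lab,
        control_mass=m_ctl,
        labeled_mass=m_lab,
        counts=counts,
        truth=truth,
        bulk_delta_labeled=simulate_irms(lab, noise_sd=irms_noise_sd, seed=seed).delta,
        bulk_delta_control=simulate_irms(ctl, noise_sd=irms_noise_sd, seed=seed + 1).delta,
    )
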