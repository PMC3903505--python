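"""Reference simulation scenarios: the study conditions the package is tested on.

Three scenario families, all desk-scale:

* the **recovery benchmark** — a 25-taxon gut-like community (log-normal
  abundances, GC 0.30-0.60), three taxa labeled (turnover 0.6, assimilation
  1.0, substrate at 0.99 atom fraction 13C), triplicate 5,000-read
  pyrosequencing of every fraction — used to ask whether the activity caller
  returns exactly the truly labeled set;
* the **null benchmark** — the same community with no labeling anywhere,
  used to calibrate the test's type-I error;
* the **gradient demonstration** — a small hand-specified community of three
  glucose consumers and two bystanders, run as "24 h" (moderate turnover,
  assimilation 0.5: hybrid heavy/light duplexes after roughly one
  generation) and "48 h" (high turnover, full assimilation) feeding windows,
  used to reproduce the qualitative DNA-profile shift: control peak in the
  light fractions, labeled peak in the heavy fractions, later time point
  heavier than the earlier one.

The parameter values here are fixed study conditions, not tunables; see the
methods note for the reasoning behind each choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import activity as _activity
from .containers import CountTable
from .gradient import BinSpec, assign_bins, pool_counts
from .sipsim import (
    CommunityProfile,
    ExperimentResult,
    LabelingScenario,
    Taxon,
    generate_community,
    simulate_experiment,
    substream,
)

__all__ = [
    "recovery_community",
    "choose_labeled",
    "early_instar_scenario",
    "null_scenario",
    "benchmark_bins",
    "run_benchmark",
    "demo_community",
    "demo_scenario",
]

#: Replicates and depth of the benchmark experiments.
BENCH_DEPTH = 5000
BENCH_REPLICATES = 3
BENCH_N_TAXA = 25
BENCH_N_LABELED = 3
BENCH_TURNOVER = 0.6


def recovery_community(seed: int, n_taxa: int = BENCH_N_TAXA) -> CommunityProfile:
    """The 25-taxon benchmark community (log-normal abundances, GC 0.30-0.60)."""
    return generate_community(
        n_taxa=n_taxa,
        abundance_model="lognormal",
        lognormal_sigma=1.0,
        gc_bounds=(0.30, 0.60),
        host_dna_fraction=0.5,
        background_fraction=0.05,
        seed=seed,
    )


def choose_labeled(community: CommunityProfile, seed: int, k: int = BENCH_N_LABELED) -> list[str]:
    """Pick the truly active taxa for a recovery run, uniformly at random."""
    rng = substream(seed, "labeled-set")
    ids = [t.id for t in community.taxa]
    return sorted(rng.choice(ids, size=k, replace=False).tolist())


def early_instar_scenario(labeled_ids: list[str], turnover: float = BENCH_TURNOVER) -> LabelingScenario:
    """Labeling window of the recovery benchmark: 3 active glucose consumers."""
    return LabelingScenario(
        substrate_af=0.99,
        duration_label="48h",
        turnover={tid: turnover for tid in labeled_ids},
        assimilation=1.0,
    )


def null_scenario() -> LabelingScenario:
    """No labeling anywhere: the type-I-error benchmark."""
    return LabelingScenario(substrate_af=0.99, duration_label="null", turnover=0.0)


def benchmark_bins() -> BinSpec:
    """Fraction pooling for the benchmark gradient.

    With GC in [0.30, 0.60] and the default BD physics, unlabeled DNA bands
    at 1.689-1.719 g/ml and fully labeled DNA at 1.725-1.754 g/ml, so on the
    default 12-fraction gradient the labeled bands fall in fractions 1-6 and
    unlabeled band centers in 7-12; the pooling mirrors how heavy fractions
    are chosen from an observed profile before scoring.
    """
    return BinSpec({
        "heavy": tuple(range(1, 7)),
        "middle": (7, 8),
        "light": (9, 10, 11, 12),
    })


@dataclass
class BenchmarkRun:
    """One simulated benchmark experiment, binned and scored."""

    experiment: ExperimentResult
    binned: CountTable
    results: pd.DataFrame  # activity_table output
    labeled_truth: set[str]

    @property
    def active_set(self) -> set[str]:
        mask = self.results["activity_class"] == "active"
        return set(self.results.index[mask])


def run_benchmark(
    seed: int,
    labeled: bool = True,
    alpha: float = 0.05,
    turnover: float = BENCH_TURNOVER,
) -> BenchmarkRun:
    """Simulate one benchmark experiment end to end and score it.

    ``labeled=False`` runs the null benchmark (turnover 0 everywhere, truth
    set empty).
    """
    community = recovery_community(seed)
    if labeled:
        ids = choose_labeled(community, seed)
        scenario = early_instar_scenario(ids, turnover=turnover)
        truth = set(ids)
    else:
        scenario = null_scenario()
        truth = set()
    exp = simulate_experiment(
        community,
        scenario,
        depth=BENCH_DEPTH,
        n_replicates=BENCH_REPLICATES,
        seed=seed,
    )
    mapping = assign_bins(exp.control_fractions, benchmark_bins())
    binned = pool_counts(exp.counts, mapping)
    results = _activity.activity_table(binned, alpha=alpha, seed=seed)
    return BenchmarkRun(experiment=exp, binned=binned, results=results, labeled_truth=truth)


# ---------------------------------------------------------------------------
# gradient demonstration


def demo_community() -> CommunityProfile:
    """Hand-specified five-taxon gut community for the gradient demonstration.

    Three glucose consumers (a, b, c — think Pantoea-, Citrobacter- and
    Clostridium-like populations) carry 80% of the bacterial DNA; two
    bystanders fill the rest. The host share is 0.30 here — the
    demonstration emulates an extract in which microbial DNA is abundant
    enough for its banding to show in the total-DNA profile, as in an
    observed gradient with a visible heavy peak (the generator's default of
    0.5 describes a more host-dominated extract whose profile is host-shaped
    everywhere).
    """
    taxa = [
        Taxon(id="consumer_a", gc=0.54, base_abundance=0.35,
              lineage={"phylum": "Proteobacteria", "genus": "GenusA"}),
        Taxon(id="consumer_b", gc=0.48, base_abundance=0.25,
              lineage={"phylum": "Proteobacteria", "genus": "GenusB"}),
        Taxon(id="consumer_c", gc=0.42, base_abundance=0.20,
              lineage={"phylum": "Firmicutes", "genus": "GenusC"}),
        Taxon(id="bystander_d", gc=0.58, base_abundance=0.12,
              lineage={"phylum": "Actinobacteria", "genus": "GenusD"}),
        Taxon(id="bystander_e", gc=0.36, base_abundance=0.08,
              lineage={"phylum": "Firmicutes", "genus": "GenusE"}),
    ]
    return CommunityProfile(taxa=taxa, host_dna_fraction=0.30, background_fraction=0.05)


_CONSUMERS = ("consumer_a", "consumer_b", "consumer_c")


def demo_scenario(duration: str) -> LabelingScenario:
    """The "24h" and "48h" feeding windows of the gradient demonstration.

    At 24 h roughly one generation has passed: about 45% of consumer DNA is
    newly made and is hybrid (one old strand), so its carbon is only ~50%
    substrate-derived. By 48 h newly divided cells have largely replaced old
    ones: 80% turnover, fully substrate-fed new DNA.
    """
    if duration == "24h":
        turnover, assimilation = 0.45, 0.5
    elif duration == "48h":
        turnover, assimilation = 0.80, 1.0
    else:
        raise ValueError(f"unknown demo duration {duration!r}")
    return LabelingScenario(
        substrate_af=0.99,
        duration_label=duration,
        turnover={t: turnover for t in _CONSUMERS},
        assimilation=assimilation,
    )
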