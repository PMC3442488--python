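"""Synthetic two-species expression studies with planted ground truth.

The generator emulates the structure of a cross-species blood-transcriptome
comparison: a small bead-array-style study A (few samples per group, probe-
level features with detection p-values, two time points) and a larger
clinical study B (many samples, two patient conditions at two time points,
gene-centered features), linked by a homolog map over a shared universe.

The statistical model matches the assumptions of the downstream moderated-t
analysis so that parameter recovery is a meaningful test: gene baselines are
uniform on the log2 scale, gene variances follow a scaled-inverse-chi-square
prior with (``variance_prior_df``, ``variance_prior_scale``) — the ground
truth for the empirical-Bayes prior fit — and noise is Gaussian.  Planted
differential-expression effects come in five classes per shared-homolog
gene: concordant (same sign in both studies), discordant (opposite signs),
study-A-only, study-B-only, and null (effect exactly zero).  Effects persist
across both time points for a configurable majority of DE genes; the rest
are active at a single random time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionStudy, HomologMap
from .enrichment import GeneSetCollection

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_two_species_study",
    "generate_gene_set_collection",
    "score_recovery",
]

CLASS_LABELS = ("concordant-DE", "discordant-DE", "A-only-DE", "B-only-DE", "null")


class ConfigurationError(ValueError):
    """A simulation configuration violates one of its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and model parameters for the two-species simulator.

    Defaults mirror the structure of the motivating comparison: ~9,325
    gene-centered murine features (4 controls, 4 animals per time point at
    6 h and 24 h), ~18,988 human features (18 controls; sepsis and septic
    shock at 24 h and 72 h), and a shared homolog universe of 7,461 genes.
    """

    n_genes_a: int = 9325
    n_genes_b: int = 18988
    n_shared: int = 7461
    n_controls_a: int = 4
    n_per_group_a: int = 4
    times_a: tuple[float, ...] = (6.0, 24.0)
    n_controls_b: int = 18
    #: (condition, time, n_samples) for every patient group in study B
    groups_b: tuple[tuple[str, float, int], ...] = (
        ("sepsis", 24.0, 32),
        ("sepsis", 72.0, 20),
        ("shock", 24.0, 67),
        ("shock", 72.0, 39),
    )
    baseline_mean_range: tuple[float, float] = (6.0, 12.0)
    variance_prior_df: float = 4.0
    variance_prior_scale: float = 0.05
    frac_shared_de: float = 0.02
    frac_exclusive_de: float = 0.01
    frac_discordant: float = 0.0015
    persistence_fraction: float = 0.9
    effect_size: float = 2.0
    probes_per_gene_max: int = 3
    probe_offset_sd: float = 0.1
    detection_dropout_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        def bad(msg):
            raise ConfigurationError(f"invalid SimulationConfig: {msg}")

        for name in (
            "n_genes_a",
            "n_genes_b",
            "n_shared",
            "n_controls_a",
            "n_per_group_a",
            "n_controls_b",
            "probes_per_gene_max",
        ):
            if getattr(self, name) < 1:
                bad(f"{name} must be >= 1")
        if self.n_shared > min(self.n_genes_a, self.n_genes_b):
            bad("n_shared must be <= min(n_genes_a, n_genes_b)")
        for name in ("frac_shared_de", "frac_exclusive_de", "frac_discordant"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad(f"{name} must lie in [0, 1]")
        if self.frac_shared_de + self.frac_exclusive_de > 1.0:
            bad("frac_shared_de + frac_exclusive_de must be <= 1")
        if self.frac_shared_de + 2 * self.frac_exclusive_de > 1.0:
            bad("frac_shared_de + exclusive fractions for both studies exceed 1")
        if self.frac_discordant > self.frac_shared_de:
            bad("frac_discordant must be <= frac_shared_de")
        if not (0.0 <= self.persistence_fraction <= 1.0):
            bad("persistence_fraction must lie in [0, 1]")
        if not (0.0 <= self.detection_dropout_rate <= 1.0):
            bad("detection_dropout_rate must lie in [0, 1]")
        if self.effect_size < 0:
            bad("effect_size must be >= 0")
        if self.variance_prior_df <= 0 or self.variance_prior_scale <= 0:
            bad("variance prior parameters must be > 0")
        if not self.baseline_mean_range[0] <= self.baseline_mean_range[1]:
            bad("baseline_mean_range must be (lo, hi) with lo <= hi")
        if len(self.times_a) < 1 or len(self.groups_b) < 1:
            bad("each study needs at least one non-control group")


@dataclass
class SyntheticTruth:
    """Planted ground truth, keyed by the homolog key (study-A gene id).

    ``classes`` labels every shared-universe gene with its planted class;
    ``effects`` lists every nonzero planted effect per (gene, study, time);
    ``dropped_a`` are shared genes whose study-A probes were planted as
    undetected and therefore leave the merged universe at the detection
    filter.
    """

    classes: pd.Series
    effects: pd.DataFrame
    dropped_a: frozenset[str] = field(default_factory=frozenset)

    def genes(self, label: str) -> set[str]:
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {label!r}; use one of {CLASS_LABELS}")
        return set(self.classes.index[self.classes == label])

    def expected_universe(self) -> set[str]:
        """Shared genes expected to survive preprocessing (dropout removed)."""
        return set(self.classes.index) - set(self.dropped_a)

    def effect(self, key: str, study: str, time: float) -> float:
        sel = self.effects[
            (self.effects["homolog_key"] == key)
            & (self.effects["study"] == study)
            & (self.effects["time"] == time)
        ]
        return float(sel["effect"].iloc[0]) if len(sel) else 0.0


def _plant_effects(config: SimulationConfig, rng: np.random.Generator, keys):
    """Assign classes, signs and per-time effects over the shared universe."""
    n = len(keys)
    n_sh = int(round(config.frac_shared_de * n))
    n_disc = min(int(round(config.frac_discordant * n)), n_sh)
    n_conc = n_sh - n_disc
    n_excl = int(round(config.frac_exclusive_de * n))
    perm = rng.permutation(n)
    blocks = {
        "concordant-DE": perm[:n_conc],
        "discordant-DE": perm[n_conc : n_conc + n_disc],
        "A-only-DE": perm[n_sh : n_sh + n_excl],
        "B-only-DE": perm[n_sh + n_excl : n_sh + 2 * n_excl],
    }
    classes = pd.Series("null", index=pd.Index(keys, name="homolog_key"), dtype=object)
    for label, idx in blocks.items():
        classes.iloc[idx] = label

    rows = []
    for label, idx in blocks.items():
        for i in idx:
            key = keys[i]
            sign_a = float(rng.choice([-1.0, 1.0]))
            sign_b = -sign_a if label == "discordant-DE" else sign_a
            for study, sign, times in (
                ("A", sign_a, config.times_a),
                ("B", sign_b, tuple(sorted({t for _, t, _ in config.groups_b}))),
            ):
                if (label == "A-only-DE" and study == "B") or (
                    label == "B-only-DE" and study == "A"
                ):
                    continue
                if rng.random() < config.persistence_fraction:
                    active = times
                else:
                    active = (times[rng.integers(len(times))],)
                for t in active:
                    rows.append(
                        {
                            "homolog_key": key,
                            "study": study,
                            "time": float(t),
                            "effect": sign * config.effect_size,
                            "label": label,
                        }
                    )
    effects = pd.DataFrame(
        rows, columns=["homolog_key", "study", "time", "effect", "label"]
    )
    return classes, effects


def _gene_matrix(rng, config, n_genes, effect_lookup, sample_plan):
    """Baselines + planted effects + Gaussian noise for one study.

    ``sample_plan`` is a list of (sample_name, group, time, is_control);
    ``effect_lookup`` maps (gene_index, time) -> effect for non-control
    samples.
    """
    lo, hi = config.baseline_mean_range
    mu = rng.uniform(lo, hi, n_genes)
    # scaled-inverse-chi-square(d0, s0^2) gene variances
    d0, s0sq = config.variance_prior_df, config.variance_prior_scale
    sigma2 = d0 * s0sq / rng.chisquare(d0, n_genes)
    names = [s[0] for s in sample_plan]
    vals = np.empty((n_genes, len(sample_plan)))
    for j, (_, group, time, is_control) in enumerate(sample_plan):
        eff = np.zeros(n_genes)
        if not is_control:
            eff = effect_lookup.get(float(time), eff)
        vals[:, j] = mu + eff + rng.normal(0.0, np.sqrt(sigma2))
    matrix = pd.DataFrame(vals, columns=names)
    samples = pd.DataFrame(
        {
            "group": [s[1] for s in sample_plan],
            "time": [s[2] for s in sample_plan],
            "is_control": [s[3] for s in sample_plan],
        },
        index=pd.Index(names, name="sample"),
    )
    return matrix, samples


def _effect_columns(effects, study, n_genes, key_pos):
    """Per-time dense effect vectors for one study, indexed by gene position."""
    out: dict[float, np.ndarray] = {}
    sub = effects[effects["study"] == study]
    for t, grp in sub.groupby("time"):
        vec = np.zeros(n_genes)
        pos = [key_pos[k] for k in grp["homolog_key"]]
        vec[pos] = grp["effect"].to_numpy()
        out[float(t)] = vec
    return out


def generate_two_species_study(
    config: SimulationConfig,
) -> tuple[ExpressionStudy, ExpressionStudy, HomologMap, SyntheticTruth]:
    """Simulate the paired studies, their homolog map, and the planted truth.

    Study A is probe-level (1..``probes_per_gene_max`` probes per gene with
    N(0, ``probe_offset_sd``²) offsets) and carries detection p-values: all
    probes of a ``detection_dropout_rate`` fraction of *null* genes are
    undetected (p > 0.01 everywhere) and vanish at the detection filter;
    every other probe is detected in all samples.  Study B is gene-centered
    (one feature per gene), emulating re-annotated probe-set definitions.
    Identical seeds yield bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_a = [str(100001 + i) for i in range(config.n_genes_a)]
    gene_b = [str(200001 + i) for i in range(config.n_genes_b)]
    shared_keys = gene_a[: config.n_shared]
    key_pos_a = {k: i for i, k in enumerate(gene_a)}
    key_pos_b_shared = {shared_keys[i]: i for i in range(config.n_shared)}

    classes, effects = _plant_effects(config, rng, shared_keys)

    # ---- study A (probe-level, detection p-values) ----
    plan_a = [(f"CTRL_A_{i+1}", "control", np.nan, True) for i in range(config.n_controls_a)]
    for t in config.times_a:
        plan_a += [
            (f"PCI_{t:g}h_{i+1}", "PCI", float(t), False)
            for i in range(config.n_per_group_a)
        ]
    eff_a = _effect_columns(effects, "A", config.n_genes_a, key_pos_a)
    mat_a_gene, samples_a = _gene_matrix(rng, config, config.n_genes_a, eff_a, plan_a)

    n_probes = rng.integers(1, config.probes_per_gene_max + 1, config.n_genes_a)
    gene_idx = np.repeat(np.arange(config.n_genes_a), n_probes)
    offsets = rng.normal(0.0, config.probe_offset_sd, gene_idx.size)
    probe_ids = [f"ILMN_{k+1:06d}" for k in range(gene_idx.size)]
    probe_vals = mat_a_gene.to_numpy()[gene_idx] + offsets[:, None]
    matrix_a = pd.DataFrame(probe_vals, index=probe_ids, columns=mat_a_gene.columns)

    null_mask = (classes == "null").to_numpy()
    dropped_shared = rng.random(config.n_shared) < config.detection_dropout_rate
    dropped_shared &= null_mask  # detection failure models unexpressed transcripts
    dropped_tail = rng.random(config.n_genes_a - config.n_shared) < (
        config.detection_dropout_rate
    )
    dropped_gene = np.concatenate([dropped_shared, dropped_tail])
    probe_dropped = dropped_gene[gene_idx]
    det = rng.uniform(0.0, 0.009, probe_vals.shape)
    det[probe_dropped, :] = rng.uniform(0.02, 1.0, (int(probe_dropped.sum()), probe_vals.shape[1]))
    detection_p = pd.DataFrame(det, index=probe_ids, columns=matrix_a.columns)

    study_a = ExpressionStudy(
        matrix=matrix_a, samples=samples_a, detection_p=detection_p, name="study_a"
    )

    # ---- study B (gene-centered features) ----
    plan_b = [(f"CTRL_B_{i+1}", "control", np.nan, True) for i in range(config.n_controls_b)]
    for cond, t, n in config.groups_b:
        plan_b += [(f"{cond.upper()}_{t:g}h_{i+1}", cond, float(t), False) for i in range(n)]
    eff_b_shared = _effect_columns(effects, "B", config.n_shared, key_pos_b_shared)
    eff_b = {
        t: np.concatenate([v, np.zeros(config.n_genes_b - config.n_shared)])
        for t, v in eff_b_shared.items()
    }
    mat_b_gene, samples_b = _gene_matrix(rng, config, config.n_genes_b, eff_b, plan_b)
    features_b = [f"ps_{g}" for g in gene_b]
    matrix_b = mat_b_gene.set_axis(features_b, axis=0)
    study_b = ExpressionStudy(matrix=matrix_b, samples=samples_b, name="study_b")

    homolog_map = HomologMap(
        probes_a=pd.DataFrame({"probe_id": probe_ids, "gene_id": [gene_a[i] for i in gene_idx]}),
        probes_b=pd.DataFrame({"probe_id": features_b, "gene_id": gene_b}),
        pairs=pd.DataFrame(
            {"gene_a": shared_keys, "gene_b": gene_b[: config.n_shared]}
        ),
    )
    truth = SyntheticTruth(
        classes=classes,
        effects=effects,
        dropped_a=frozenset(np.array(shared_keys)[dropped_shared]),
    )
    return study_a, study_b, homolog_map, truth


def generate_gene_set_collection(
    truth: SyntheticTruth,
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 40),
    enrichment_fraction: float = 0.5,
    seed: int | None = None,
    de_member_fraction: float = 0.5,
) -> GeneSetCollection:
    """Build a local gene-set collection over the synthetic shared universe.

    A ``enrichment_fraction`` share of sets deliberately over-represents
    concordant-DE genes (``de_member_fraction`` of their members drawn from
    that class, the rest uniformly); remaining sets are uniform draws and
    should show flat enrichment p-values.
    """
    universe = np.array(sorted(truth.classes.index))
    if universe.size == 0:
        raise ValueError("generate_gene_set_collection: truth is empty")
    lo, hi = set_size_range
    if not (1 <= lo <= hi):
        raise ValueError("set_size_range must be (lo, hi) with 1 <= lo <= hi")
    if hi > universe.size:
        raise ValueError(
            f"set size {hi} exceeds the universe of {universe.size} genes"
        )
    rng = np.random.default_rng(seed)
    de_genes = np.array(sorted(truth.genes("concordant-DE")))
    n_enriched = int(round(enrichment_fraction * n_sets))
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        enriched = i < n_enriched and de_genes.size > 0
        if enriched:
            n_de = min(int(round(de_member_fraction * size)), de_genes.size)
            de_part = rng.choice(de_genes, n_de, replace=False)
            rest_pool = np.setdiff1d(universe, de_part)
            rest = rng.choice(rest_pool, size - n_de, replace=False)
            members = np.concatenate([de_part, rest])
        else:
            members = rng.choice(universe, size, replace=False)
        name = f"{'enriched' if enriched else 'background'}_set_{i+1:02d}"
        sets[name] = frozenset(members)
        descriptions[name] = (
            "over-represents concordant-DE genes" if enriched else "uniform draw"
        )
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def score_recovery(
    truth: SyntheticTruth, degc: set, concordance: pd.DataFrame | None = None
) -> dict[str, float]:
    """Score a DEGC call (and optionally its sign partition) against truth.

    Returns sensitivity/precision of DEGC for planted concordant genes and,
    when a concordance table is given, the fraction of planted-discordant
    DEGC members recovered by the discordant partition.
    """
    degc = {str(g) for g in degc}
    conc = truth.genes("concordant-DE")
    disc = truth.genes("discordant-DE")
    planted = conc | disc
    out: dict[str, float] = {
        "degc_size": float(len(degc)),
        "concordant_sensitivity": (len(degc & conc) / len(conc)) if conc else float("nan"),
        "degc_precision": (len(degc & planted) / len(degc)) if degc else float("nan"),
    }
    if concordance is not None:
        called_disc = set(
            concordance.index[concordance["concordance"] == "discordant"]
        )
        planted_disc_in_degc = disc & degc
        out["discordant_recovery"] = (
            len(called_disc & planted_disc_in_degc) / len(planted_disc_in_degc)
            if planted_disc_in_degc
            else float("nan")
        )
        out["discordant_called"] = float(len(called_disc))
    return out
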