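"""Candidate-gene extraction cascade.

The study asks which genes a galactose insult turns on (or off) in the rat
lens and which of those changes an effective HAT-inhibitor treatment undoes.
The cascade proceeds through:

1. low-signal filtering over the galactose arrays;
2. per-replicate differential screens of each galactose array against the
   single control array, summarised in Venn partitions;
3. a *reversal screen*: genes changed vs control (p < α) in at least one
   galactose array and changed back (p < α) in at least one effective
   treatment array, run at the descending thresholds α ∈ {0.1, 0.05, 0.01};
4. a *median screen* that replaces the per-replicate galactose signal with a
   per-probe median pseudo-array across the six galactose arrays;
5. monotherapy subtraction for the two combination treatments (drop genes
   that also respond to either ineffective single agent) and a ≥2-fold gate
   for the TH1834 branch (its single agent is itself the effective drug, so
   no subtraction is possible);
6. assembly of the per-treatment candidate sets into one flagged union.

All thresholds are strict (p < α); fold gates keep ≥ min_fold.  Each stage
returns a :class:`~lensgex.io.GeneSet` whose provenance records the filter
applied, so every reported count can be reconstructed from the emitted sets.

:class:`ReversalCascade` wraps the whole procedure as a model object:
``ReversalCascade(matrix, probes, config).fit()`` returns a
:class:`CascadeResults` with per-stage sets, counts, and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .errors import ConfigurationError
from .io import CascadeConfig, GeneSet, ProbeLevelArray, SignalMatrix
from .screen import group_contrast, low_signal_filter, pair_contrast_frame
from .simulate import TruthTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# probe helpers
# ---------------------------------------------------------------------------

def _restrict(array: ProbeLevelArray, genes: Sequence[str]) -> ProbeLevelArray:
    present = set(array.probes.index)
    keep = [g for g in genes if g in present]
    return ProbeLevelArray(array.sample_id, array.probes.loc[keep])


def median_probe_array(
    probes: Mapping[str, ProbeLevelArray],
    samples: Sequence[str],
    genes: Sequence[str] | None = None,
    name: str = "galactose_median",
) -> ProbeLevelArray:
    """Per-probe median across several arrays — the galactose representative.

    Taking the median probe-by-probe keeps a within-array spread for the
    pseudo-array, so the same probe-level t-test machinery applies to
    contrasts against it.
    """
    stack = [probes[s].probes for s in samples]
    genes = list(genes) if genes is not None else list(stack[0].index)
    aligned = np.stack([df.loc[genes].to_numpy(dtype=float) for df in stack])
    med = np.nanmedian(aligned, axis=0)
    return ProbeLevelArray(name, pd.DataFrame(med, index=pd.Index(genes, name="gene_id"),
                                              columns=stack[0].columns))


def _qualify(
    frame: pd.DataFrame, alpha: float, direction: str
) -> pd.Series:
    """Boolean qualification p < alpha with the required sign (strict)."""
    want = "up" if direction == "up" else "down"
    return (frame["p_value"] < alpha) & (frame["direction"] == want)


def _fold_qualify(fc: pd.Series, fold: float, direction: str) -> pd.Series:
    return fc > fold if direction == "up" else fc < 1.0 / fold


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------

def per_replicate_differential(
    matrix: SignalMatrix,
    probes: Mapping[str, ProbeLevelArray] | None,
    control_sample: str,
    galactose_sample: str,
    alpha: float,
    fold_threshold: float = 1.5,
) -> GeneSet:
    """Genes differentially expressed (either direction) between one galactose
    array and the control array, at p < alpha.

    Probe mode runs the probe-level t-test; without probe data the screen
    degrades to a two-sided fold-change criterion with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    genes = matrix.gene_ids
    if probes is not None:
        frame = pair_contrast_frame(
            _restrict(probes[control_sample], genes), _restrict(probes[galactose_sample], genes)
        )
        hits = frame.index[(frame["p_value"] < alpha) & (frame["direction"] != "flat")]
    else:
        log.warning("per_replicate_differential: no probe data, fold-only mode")
        frame = group_contrast(matrix, [control_sample], [galactose_sample])
        fc = frame["fold_change"]
        hits = frame.index[(fc > fold_threshold) | (fc < 1.0 / fold_threshold)]
    return GeneSet(
        f"diff_{galactose_sample}",
        frozenset(hits),
        [{
            "operation": "per_replicate_differential",
            "params": {"alpha": alpha, "control": control_sample, "galactose": galactose_sample,
                       "mode": "probe" if probes is not None else "fold"},
            "inputs": ["signal_matrix"],
        }],
    )


def intersect_replicate_sets(sets: Sequence[GeneSet]) -> tuple[GeneSet, dict[str, int]]:
    """Intersection of replicate hit sets plus exclusive Venn-region counts.

    The partition maps each non-empty subset of input-set names (joined with
    ``&``) to the number of genes belonging to *exactly* those sets; region
    counts sum to the size of the union.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets to intersect")
    union = frozenset().union(*(s.members for s in sets))
    inter = sets[0].members
    for s in sets[1:]:
        inter = inter & s.members
    partition: dict[str, int] = {}
    names = [s.name for s in sets]
    for r in range(1, len(sets) + 1):
        for combo in combinations(range(len(sets)), r):
            inside = set.intersection(*(set(sets[i].members) for i in combo))
            for j in range(len(sets)):
                if j not in combo:
                    inside -= sets[j].members
            partition["&".join(names[i] for i in combo)] = len(inside)
    assert sum(partition.values()) == len(union)
    out = GeneSet(
        "replicate_intersection",
        inter,
        [{
            "operation": "intersect_replicate_sets",
            "params": {"inputs": names, "sizes": [len(s) for s in sets]},
            "inputs": names,
        }],
    )
    return out, partition


def reversal_screen(
    matrix: SignalMatrix,
    probes: Mapping[str, ProbeLevelArray] | None,
    direction: str = "up",
    alpha: float = 0.1,
    config: CascadeConfig | None = None,
    days: Sequence[int] | None = None,
) -> GeneSet:
    """Genes changed by galactose and changed back by an effective treatment.

    For ``direction='up'`` a gene qualifies when it is up vs control
    (p < alpha) in at least one galactose array *and* down (p < alpha) in at
    least one effective-treatment array relative to a galactose array in
    which it qualified.  ``direction='down'`` mirrors the signs.  ``days``
    optionally restricts the galactose arrays to Day 4 or Day 6.
    """
    config = config or CascadeConfig()
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    control = _control_sample(matrix)
    gal = _galactose_samples(matrix, days)
    treatments = _treatment_samples(matrix, config.effective_treatments)
    genes = matrix.gene_ids
    anti = "down" if direction == "up" else "up"

    if probes is not None:
        qual_gal = {}
        for g in gal:
            frame = pair_contrast_frame(_restrict(probes[control], genes), _restrict(probes[g], genes))
            qual_gal[g] = _qualify(frame, alpha, direction)
        reversed_any = pd.Series(False, index=pd.Index(genes))
        for g in gal:
            down_any_t = pd.Series(False, index=pd.Index(genes))
            for t in treatments:
                frame = pair_contrast_frame(_restrict(probes[g], genes), _restrict(probes[t], genes))
                down_any_t |= _qualify(frame, alpha, anti)
            reversed_any |= qual_gal[g] & down_any_t
        hits = reversed_any.index[reversed_any]
    else:
        log.warning("reversal_screen: no probe data, fold-only mode")
        fold = config.temporal_fold
        reversed_any = pd.Series(False, index=pd.Index(genes))
        for g in gal:
            up_fc = group_contrast(matrix, [control], [g])["fold_change"]
            up_q = _fold_qualify(up_fc, fold, direction)
            down_any_t = pd.Series(False, index=pd.Index(genes))
            for t in treatments:
                t_fc = group_contrast(matrix, [g], [t])["fold_change"]
                down_any_t |= _fold_qualify(t_fc, fold, anti)
            reversed_any |= up_q & down_any_t
        hits = reversed_any.index[reversed_any]
    return GeneSet(
        f"reversal_{direction}_a{alpha:g}" + (f"_d{'+'.join(map(str, days))}" if days else ""),
        frozenset(hits),
        [{
            "operation": "reversal_screen",
            "params": {"direction": direction, "alpha": alpha, "days": list(days) if days else None,
                       "treatments": list(config.effective_treatments)},
            "inputs": ["signal_matrix"],
        }],
    )


def day_overlap(set_day4: GeneSet, set_day6: GeneSet) -> tuple[GeneSet, GeneSet]:
    """Union and intersection of the Day-4 and Day-6 reversal sets."""
    step = {
        "operation": "day_overlap",
        "params": {"day4_size": len(set_day4), "day6_size": len(set_day6)},
        "inputs": [set_day4.name, set_day6.name],
    }
    union = GeneSet("day_union", set_day4.members | set_day6.members, [step])
    inter = GeneSet("day_intersection", set_day4.members & set_day6.members, [step])
    return union, inter


def median_reversal_screen(
    matrix: SignalMatrix,
    probes: Mapping[str, ProbeLevelArray] | None = None,
    alpha: float = 0.1,
    config: CascadeConfig | None = None,
    direction: str = "up",
    treatments: Sequence[str] | None = None,
    per_treatment: bool = False,
):
    """Reversal screen against the median galactose representative.

    The galactose side collapses to one representative: probe mode builds a
    per-probe median pseudo-array over the six galactose arrays; gene mode
    takes the median signal.  A gene qualifies as galactose-responsive when
    (probe mode) at least ``config.median_min_up`` of the six galactose
    arrays individually differ from control at p < alpha in the screened
    direction, or (gene mode) the median fold vs control exceeds the
    configured fold threshold; it must then be reversed (p < alpha, or fold
    in gene mode) in a treatment array relative to the representative.

    Returns the union :class:`GeneSet`, or a dict of per-treatment sets when
    ``per_treatment`` is true.
    """
    config = config or CascadeConfig()
    control = _control_sample(matrix)
    gal = _galactose_samples(matrix, None)
    if len(gal) < 6:
        raise ConfigurationError(f"median screen needs the 6 galactose samples, found {len(gal)}")
    treatments = list(treatments) if treatments is not None else list(config.effective_treatments)
    present = _treatment_samples(matrix, treatments)
    genes = matrix.gene_ids
    anti = "down" if direction == "up" else "up"

    if probes is not None:
        n_qual = pd.Series(0, index=pd.Index(genes))
        for g in gal:
            frame = pair_contrast_frame(_restrict(probes[control], genes), _restrict(probes[g], genes))
            n_qual += _qualify(frame, alpha, direction).astype(int)
        gal_ok = n_qual >= config.median_min_up
        rep = median_probe_array(probes, gal, genes)
        per_t = {}
        for t in present:
            frame = pair_contrast_frame(rep, _restrict(probes[t], genes))
            per_t[t] = gal_ok & _qualify(frame, alpha, anti)
    else:
        log.warning("median_reversal_screen: no probe data, fold-only mode")
        med = matrix.values[gal].median(axis=1)
        ctrl = matrix.values[control]
        fc_gal = med.clip(lower=config.epsilon) / ctrl.clip(lower=config.epsilon)
        gal_ok = _fold_qualify(fc_gal, config.temporal_fold, direction)
        per_t = {}
        for t in present:
            fc_t = matrix.values[t].clip(lower=config.epsilon) / med.clip(lower=config.epsilon)
            per_t[t] = gal_ok & _fold_qualify(fc_t, config.temporal_fold, anti)

    def _mk(name: str, mask: pd.Series, treatment: str | None) -> GeneSet:
        return GeneSet(
            name,
            frozenset(mask.index[mask]),
            [{
                "operation": "median_reversal_screen",
                "params": {"direction": direction, "alpha": alpha, "treatment": treatment,
                           "min_up": config.median_min_up,
                           "mode": "probe" if probes is not None else "fold"},
                "inputs": ["signal_matrix"],
            }],
        )

    sets = {t: _mk(f"median_{direction}_{t}", mask, t) for t, mask in per_t.items()}
    if per_treatment:
        return sets
    any_t = pd.Series(False, index=pd.Index(genes))
    for mask in per_t.values():
        any_t |= mask
    return _mk(f"median_{direction}", any_t, None)


def monotherapy_subtraction(combo_set: GeneSet, mono_sets: Sequence[GeneSet]) -> GeneSet:
    """Drop combo-responsive genes that also respond to a component single agent."""
    subtracted = frozenset().union(*(m.members for m in mono_sets)) if mono_sets else frozenset()
    kept = combo_set.members - subtracted
    return combo_set.derive(
        f"{combo_set.name}_minus_mono",
        kept,
        {
            "operation": "monotherapy_subtraction",
            "params": {
                "mono_sets": [m.name for m in mono_sets],
                "subtracted": len(combo_set.members & subtracted),
            },
            "inputs": [combo_set.name] + [m.name for m in mono_sets],
        },
    )


def fold_gate(
    gene_set: GeneSet,
    matrix: SignalMatrix,
    treatment_sample: str,
    min_fold: float = 2.0,
    direction: str = "up",
    config: CascadeConfig | None = None,
) -> GeneSet:
    """Keep genes whose treatment-vs-galactose-representative change is at
    least ``min_fold`` in the reversal direction.

    The galactose representative is the per-gene median signal of the six
    galactose arrays.  For up-reversed genes the gate keeps
    representative/treatment ≥ min_fold; the down arm mirrors it.
    """
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    config = config or CascadeConfig()
    if treatment_sample not in matrix.sample_ids:
        raise ConfigurationError(f"treatment sample {treatment_sample!r} absent from matrix")
    gal = _galactose_samples(matrix, None)
    med = matrix.values[gal].median(axis=1).clip(lower=config.epsilon)
    treat = matrix.values[treatment_sample].clip(lower=config.epsilon)
    ratio = (med / treat) if direction == "up" else (treat / med)
    if min_fold == 1:
        # any change is >= 1-fold in magnitude, so a 1-fold gate excludes nothing
        genes = list(gene_set.members)
    else:
        genes = [g for g in gene_set.members if g in ratio.index and ratio[g] >= min_fold]
    return gene_set.derive(
        f"{gene_set.name}_fold{min_fold:g}",
        genes,
        {
            "operation": "fold_gate",
            "params": {"treatment": treatment_sample, "min_fold": min_fold, "direction": direction},
            "inputs": [gene_set.name],
        },
    )


def assemble_candidates(
    per_treatment_sets: Mapping[str, GeneSet],
) -> tuple[GeneSet, pd.DataFrame]:
    """Union of per-treatment candidate sets with per-treatment membership flags."""
    if not per_treatment_sets:
        raise ValueError("assemble_candidates: no input sets")
    union = sorted(frozenset().union(*(s.members for s in per_treatment_sets.values())))
    flags = pd.DataFrame(
        {t: [g in s for g in union] for t, s in per_treatment_sets.items()},
        index=pd.Index(union, name="gene_id"),
    )
    out = GeneSet(
        "candidates",
        frozenset(union),
        [{
            "operation": "assemble_candidates",
            "params": {t: len(s) for t, s in per_treatment_sets.items()},
            "inputs": [s.name for s in per_treatment_sets.values()],
        }],
    )
    return out, flags


# ---------------------------------------------------------------------------
# sample-layout helpers
# ---------------------------------------------------------------------------

def _control_sample(matrix: SignalMatrix) -> str:
    ctrl = matrix.samples_where(condition="control")
    if len(ctrl) != 1:
        raise ConfigurationError(f"expected exactly one control sample, found {ctrl}")
    return ctrl[0]


def _galactose_samples(matrix: SignalMatrix, days: Sequence[int] | None) -> list[str]:
    if days is None:
        gal = matrix.samples_where(condition="galactose")
    else:
        gal = [s for d in days for s in matrix.samples_where(condition="galactose", day=d)]
    if not gal:
        raise ConfigurationError("no galactose samples in matrix")
    return gal


def _treatment_samples(matrix: SignalMatrix, wanted: Sequence[str]) -> list[str]:
    present = []
    for t in wanted:
        s = matrix.samples_where(condition="treated", treatment=t)
        if not s:
            raise ConfigurationError(f"treatment sample {t!r} missing from matrix")
        present.extend(s)
    return present


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

class ReversalCascade:
    """The full candidate-extraction cascade as a fit-able model.

    Parameters
    ----------
    matrix : SignalMatrix
        Gene-level signals for the 13-array layout.
    probes : mapping sample_id -> ProbeLevelArray, optional
        Probe-level data enabling single-array p-values; without it the
        cascade runs in fold-change-only mode.
    config : CascadeConfig, optional
    """

    def __init__(
        self,
        matrix: SignalMatrix,
        probes: Mapping[str, ProbeLevelArray] | None = None,
        config: CascadeConfig | None = None,
    ):
        self.matrix = matrix
        self.probes = dict(probes) if probes is not None else None
        self.config = config or CascadeConfig()

    def fit(self, alpha: float | None = None) -> "CascadeResults":
        cfg = self.config
        alpha = alpha if alpha is not None else cfg.alpha
        control = _control_sample(self.matrix)
        gal_scope = _galactose_samples(self.matrix, None)
        filtered = low_signal_filter(self.matrix, cfg.low_signal_cutoff, scope=gal_scope)

        # per-replicate screens + Venn partitions per day
        replicate_sets: dict[int, list[GeneSet]] = {}
        intersections: dict[int, GeneSet] = {}
        venns: dict[int, dict[str, int]] = {}
        for day in (4, 6):
            day_samples = _galactose_samples(filtered, [day])
            sets = [
                per_replicate_differential(filtered, self.probes, control, s, alpha,
                                           fold_threshold=cfg.temporal_fold)
                for s in day_samples
            ]
            replicate_sets[day] = sets
            if len(sets) >= 2:
                intersections[day], venns[day] = intersect_replicate_sets(sets)

        # reversal screens at every configured threshold
        reversal: dict[str, dict[float, GeneSet]] = {"up": {}, "down": {}}
        for direction in ("up", "down"):
            for a in sorted(cfg.alpha_levels, reverse=True):
                reversal[direction][a] = reversal_screen(
                    filtered, self.probes, direction, a, cfg
                )

        # day-split reversal sets and their overlap at the working alpha
        day_sets: dict[str, dict] = {}
        for direction in ("up", "down"):
            s4 = reversal_screen(filtered, self.probes, direction, alpha, cfg, days=[4])
            s6 = reversal_screen(filtered, self.probes, direction, alpha, cfg, days=[6])
            union, inter = day_overlap(s4, s6)
            day_sets[direction] = {"day4": s4, "day6": s6, "union": union, "intersection": inter}

        # median screen per effective treatment
        median_sets: dict[str, GeneSet] = median_reversal_screen(
            filtered, self.probes, alpha, cfg, "up", per_treatment=True
        )
        mono_needed = sorted({m for monos in cfg.combo_components.values() for m in monos})
        mono_altered: dict[str, GeneSet] = median_reversal_screen(
            filtered, self.probes, alpha, cfg, "up", treatments=mono_needed, per_treatment=True
        )

        candidates: dict[str, GeneSet] = {}
        subtracted: dict[str, GeneSet] = {}
        for treatment in cfg.effective_treatments:
            base = median_sets[treatment]
            if treatment in cfg.combo_components:
                monos = [mono_altered[m] for m in cfg.combo_components[treatment]]
                subtracted[treatment] = monotherapy_subtraction(base, monos)
                candidates[treatment] = subtracted[treatment]
            else:
                candidates[treatment] = fold_gate(
                    base, filtered, treatment, cfg.th1834_fold, "up", cfg
                )
        union, flags = assemble_candidates(candidates)

        return CascadeResults(
            model=self,
            alpha=alpha,
            filtered=filtered,
            replicate_sets=replicate_sets,
            replicate_intersections=intersections,
            venn_partitions=venns,
            reversal=reversal,
            day_sets=day_sets,
            median_sets=median_sets,
            mono_altered=mono_altered,
            subtracted=subtracted,
            candidates=candidates,
            candidate_union=union,
            membership=flags,
        )


@dataclass
class CascadeResults:
    """Per-stage gene sets and counts from one cascade run."""

    model: ReversalCascade
    alpha: float
    filtered: SignalMatrix
    replicate_sets: dict[int, list[GeneSet]]
    replicate_intersections: dict[int, GeneSet]
    venn_partitions: dict[int, dict[str, int]]
    reversal: dict[str, dict[float, GeneSet]]
    day_sets: dict[str, dict]
    median_sets: dict[str, GeneSet]
    mono_altered: dict[str, GeneSet]
    subtracted: dict[str, GeneSet]
    candidates: dict[str, GeneSet]
    candidate_union: GeneSet
    membership: pd.DataFrame

    # -- bookkeeping -------------------------------------------------------
    @property
    def stage_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {
            "genes_total": self.model.matrix.shape[0],
            "genes_retained": self.filtered.shape[0],
        }
        for day, sets in self.replicate_sets.items():
            for s in sets:
                counts[f"day{day}_{s.name}"] = len(s)
            if day in self.replicate_intersections:
                counts[f"day{day}_intersection"] = len(self.replicate_intersections[day])
        for direction, by_alpha in self.reversal.items():
            for a, s in by_alpha.items():
                counts[f"reversal_{direction}_p{a:g}"] = len(s)
        for direction, d in self.day_sets.items():
            counts[f"reversal_{direction}_day4"] = len(d["day4"])
            counts[f"reversal_{direction}_day6"] = len(d["day6"])
            counts[f"reversal_{direction}_day_union"] = len(d["union"])
            counts[f"reversal_{direction}_day_intersection"] = len(d["intersection"])
        for t, s in self.median_sets.items():
            counts[f"median_{t}"] = len(s)
        for t, s in self.candidates.items():
            counts[f"candidates_{t}"] = len(s)
        counts["candidates_union"] = len(self.candidate_union)
        return counts

    # -- truth-based diagnostics -------------------------------------------
    def sensitivity(self, truth: TruthTable, label: str = "galactose_up_reversed") -> float:
        """Fraction of planted reversed genes recovered in the candidate union."""
        planted = set(truth.genes_of(label))
        if not planted:
            return float("nan")
        return len(planted & self.candidate_union.members) / len(planted)

    def confounder_specificity(self, truth: TruthTable, label: str = "monotherapy_confounded") -> float:
        """Fraction of planted monotherapy-confounded genes kept *out* of the
        combination-treatment candidate sets."""
        planted = set(truth.genes_of(label))
        if not planted:
            return float("nan")
        combo_union: set[str] = set()
        for t, s in self.candidates.items():
            if t in self.model.config.combo_components:
                combo_union |= s.members
        return 1.0 - len(planted & combo_union) / len(planted)

    def summary(self) -> SimpleTable:
        rows = [[k, str(v)] for k, v in self.stage_counts.items()]
        return SimpleTable(
            rows,
            headers=["stage", "genes"],
            title=f"Reversal cascade (alpha={self.alpha:g})",
        )

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "stage_counts": self.stage_counts,
            "venn_partitions": {str(k): v for k, v in self.venn_partitions.items()},
            "candidates": {t: sorted(s.members) for t, s in self.candidates.items()},
            "candidate_union": sorted(self.candidate_union.members),
        }
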