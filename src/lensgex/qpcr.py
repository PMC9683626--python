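"""Relative qPCR quantification and candidate confirmation.

Expression of each target is normalised to the Gapdh reference per replicate
via the 2^-ΔCt rule — ``relative_expression = 2^(Ct_reference − Ct_target)``,
with the amplification efficiency fixed at 2 (no standard-curve correction).
Group comparisons against the galactose group use a two-tailed unpaired
equal-variance Student's t-test on the normalised values, significant at
p < 0.05.

A candidate gene is *confirmed* for a treatment when its expression shows a
significant decrease vs galactose in the treated group AND a significant
difference in the untreated control (the galactose induction itself), AND —
for combination treatments — no significant decrease under either component
monotherapy.  "Significant decrease" enforces direction: p below the
threshold and a lower treated mean, not p alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.iolib.table import SimpleTable

from .errors import ConfigurationError, DegenerateInputError, FormatError
from .io import GeneSet

REQUIRED_COLUMNS = ("gene", "group", "replicate", "ct_target", "ct_reference")


@dataclass
class ConfirmationRule:
    """Per-treatment confirmation pattern for qPCR candidates."""

    alpha: float = 0.05
    treatments: tuple[str, ...] = ("C646+CPTH2", "CBP30+CPTH2", "TH1834")
    combo_components: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "C646+CPTH2": ("C646", "CPTH2"),
            "CBP30+CPTH2": ("CBP30", "CPTH2"),
        }
    )
    galactose_group: str = "galactose"
    control_group: str = "control"
    require_control_significant: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha outside (0, 1)")


def validate_qpcr_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"qPCR table lacks columns {missing}")
    bad = table[(table["ct_target"] <= 0) | (table["ct_reference"] <= 0)]
    if not bad.empty:
        raise FormatError("Ct values must be positive")
    return table


def relative_expression(ct_target, ct_reference):
    """2^(Ct_reference − Ct_target): target expression normalised to the reference."""
    return np.exp2(np.asarray(ct_reference, dtype=float) - np.asarray(ct_target, dtype=float))


def normalized_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append per-replicate normalised expression; drop rows lacking a reference Ct."""
    table = validate_qpcr_table(table).copy()
    usable = table["ct_reference"].notna() & table["ct_target"].notna()
    if not usable.all():
        import logging

        logging.getLogger(__name__).warning(
            "normalized_table: %d record(s) without reference Ct skipped", (~usable).sum()
        )
    table = table[usable].copy()
    table["expression"] = relative_expression(table["ct_target"], table["ct_reference"])
    return table


def group_expression(table: pd.DataFrame, gene: str, group: str) -> np.ndarray:
    sub = table[(table["gene"] == gene) & (table["group"] == group)]
    return sub["expression"].to_numpy(dtype=float)


def group_test(table: pd.DataFrame, gene: str, group_a: str,
               galactose_group: str = "galactose") -> float:
    """Two-tailed unpaired Student's t between a group and galactose.

    Operates on per-replicate normalised expression.  Fewer than two
    replicates on either side is a degenerate input.
    """
    a = group_expression(table, gene, group_a)
    g = group_expression(table, gene, galactose_group)
    if len(a) < 2 or len(g) < 2:
        raise DegenerateInputError(
            f"group_test needs >= 2 replicates per side for {gene!r} "
            f"({group_a}: {len(a)}, {galactose_group}: {len(g)})"
        )
    if np.allclose(a, a[0]) and np.allclose(g, g[0]):
        # zero variance on both sides: p is the limit of the t statistic
        return 1.0 if np.isclose(a[0], g[0]) else 0.0
    t, p = stats.ttest_ind(a, g, equal_var=True)
    return float(p)


def _significant_change(table: pd.DataFrame, gene: str, group: str, rule: ConfirmationRule,
                        direction: str | None = "down") -> bool:
    a = group_expression(table, gene, group)
    g = group_expression(table, gene, rule.galactose_group)
    p = group_test(table, gene, group, rule.galactose_group)
    if p >= rule.alpha:
        return False
    if direction == "down":
        return a.mean() < g.mean()
    if direction == "up":
        return a.mean() > g.mean()
    return True


def confirm_candidates(
    table: pd.DataFrame,
    rule: ConfirmationRule | None = None,
    genes: Sequence[str] | None = None,
) -> dict[str, GeneSet]:
    """Apply the confirmation pattern per treatment.

    Returns a mapping treatment → confirmed :class:`GeneSet`.
    """
    rule = rule or ConfirmationRule()
    table = normalized_table(table)
    present_groups = set(table["group"].unique())
    for t in rule.treatments:
        if t not in present_groups:
            raise ConfigurationError(f"treatment group {t!r} absent from qPCR table")
        for mono in rule.combo_components.get(t, ()):
            if mono not in present_groups:
                raise ConfigurationError(f"monotherapy group {mono!r} (for {t!r}) absent")
    if rule.galactose_group not in present_groups:
        raise ConfigurationError(f"galactose group {rule.galactose_group!r} absent")

    genes = list(genes) if genes is not None else sorted(table["gene"].unique())
    confirmed: dict[str, GeneSet] = {}
    for treatment in rule.treatments:
        hits = []
        for gene in genes:
            if not _significant_change(table, gene, treatment, rule, "down"):
                continue
            if rule.require_control_significant and not _significant_change(
                table, gene, rule.control_group, rule, None
            ):
                continue
            monos = rule.combo_components.get(treatment, ())
            if any(_significant_change(table, gene, m, rule, "down") for m in monos):
                continue
            hits.append(gene)
        confirmed[treatment] = GeneSet(
            f"confirmed_{treatment}",
            frozenset(hits),
            [{
                "operation": "confirm_candidates",
                "params": {"treatment": treatment, "alpha": rule.alpha,
                           "monotherapies": list(rule.combo_components.get(treatment, ()))},
                "inputs": ["qpcr_table"],
            }],
        )
    return confirmed


class QpcrExperiment:
    """qPCR confirmation experiment as a fit-able model.

    ``fit()`` normalises the Ct table, tests every (gene, group) against
    galactose, and applies the confirmation rule.
    """

    def __init__(self, table: pd.DataFrame, rule: ConfirmationRule | None = None):
        self.table = validate_qpcr_table(table)
        self.rule = rule or ConfirmationRule()

    def fit(self) -> "QpcrResults":
        norm = normalized_table(self.table)
        genes = sorted(norm["gene"].unique())
        groups = [g for g in norm["group"].unique() if g != self.rule.galactose_group]
        rows = []
        for gene in genes:
            for group in groups:
                expr = group_expression(norm, gene, group)
                try:
                    p = group_test(norm, gene, group, self.rule.galactose_group)
                except DegenerateInputError:
                    p = float("nan")
                se = expr.std(ddof=1) / np.sqrt(len(expr)) if len(expr) > 1 else float("nan")
                rows.append((gene, group, expr.mean(), se, p))
        tests = pd.DataFrame(rows, columns=["gene", "group", "mean_expression", "se", "p_vs_galactose"])
        confirmed = confirm_candidates(norm, self.rule, genes)
        return QpcrResults(self, tests, confirmed)


@dataclass
class QpcrResults:
    model: QpcrExperiment
    tests: pd.DataFrame
    confirmed: dict[str, GeneSet]

    def summary(self) -> SimpleTable:
        rows = [[t, str(len(s)), ", ".join(sorted(s.members)) or "-"]
                for t, s in self.confirmed.items()]
        return SimpleTable(
            rows,
            headers=["treatment", "confirmed", "genes"],
            title=f"qPCR-confirmed candidates (p<{self.model.rule.alpha:g} vs galactose)",
        )
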