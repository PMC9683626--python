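"""Synthetic data with planted ground truth for every pipeline stage.

Three generators emulate the study's three data streams:

* :func:`simulate_microarray` — probe-level microarray data for the 13-array
  layout (one untreated control, three galactose Day-4 arrays, three
  galactose Day-6 arrays, and six single treated arrays: C646, CBP30, CPTH2,
  C646+CPTH2, CBP30+CPTH2, TH1834), with log-normal probe noise and planted
  gene classes;
* :func:`simulate_lens_images` — paired before/after top-view lens
  photographs: a bright disk on a dark background whose outer cortical
  annulus carries a planted opacity increment;
* :func:`simulate_qpcr` — Ct tables for a target gene panel against a
  constant-in-expectation reference (Gapdh).

A fixed seed fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError
from .io import ProbeLevelArray, SignalMatrix

#: planted gene classes, in planting order
GENE_CLASSES = (
    "galactose_up_reversed",
    "monotherapy_confounded",
    "early_plateau",
    "monotonic_rise",
    "early_peak",
    "late_rise",
    "galactose_down_restored",
)

CONTROL_SAMPLE = "control"
GALACTOSE_SAMPLES = ("gal_d4_r1", "gal_d4_r2", "gal_d4_r3", "gal_d6_r1", "gal_d6_r2", "gal_d6_r3")
MONO_TREATMENTS = ("C646", "CBP30", "CPTH2")
COMBO_TREATMENTS = ("C646+CPTH2", "CBP30+CPTH2")
TREATMENT_SAMPLES = ("C646", "CBP30", "CPTH2", "C646+CPTH2", "CBP30+CPTH2", "TH1834")
ALL_SAMPLES = (CONTROL_SAMPLE,) + GALACTOSE_SAMPLES + TREATMENT_SAMPLES


@dataclass
class SimulationDesign:
    """Parameters of the planted microarray simulation.

    Per-gene baselines are drawn once on the log2 scale; probe intensities
    are log-normal around the class-determined per-condition mean (Gaussian
    noise of ``probe_sd`` on log2, exponentiated).  ``galactose_effect`` is
    the log2 step a galactose-responsive gene takes; ``step2_effect`` is the
    additional Day-4→Day-6 log2 step for the temporal classes.
    """

    n_genes: int = 5000
    probes_per_gene: int = 10
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    probe_sd: float = 0.4
    galactose_effect: float = 1.5
    step2_effect: float = 1.0
    class_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "galactose_up_reversed": 70,
            "monotherapy_confounded": 30,
            "early_plateau": 40,
            "monotonic_rise": 40,
            "early_peak": 40,
            "late_rise": 40,
            "galactose_down_restored": 40,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_sizes) - set(GENE_CLASSES)
        if unknown:
            raise DesignError(f"unknown gene classes: {sorted(unknown)}")
        if sum(self.class_sizes.values()) > self.n_genes:
            raise DesignError("class sizes exceed n_genes")
        if self.probes_per_gene < 2:
            raise DesignError("need >= 2 probes per gene")
        for up_class in ("galactose_up_reversed", "monotherapy_confounded"):
            if self.class_sizes.get(up_class, 0) and self.galactose_effect <= 0:
                raise DesignError("effect size for up classes must be > 0")

    def with_seed(self, seed: int) -> "SimulationDesign":
        return replace(self, seed=seed)


@dataclass
class TruthTable:
    """Planted class label and per-sample expected log2 expression per gene."""

    labels: pd.Series  # gene_id -> class name ("null" for unplanted genes)
    expected_log2: pd.DataFrame  # genes x samples

    def __post_init__(self) -> None:
        if not self.labels.index.equals(self.expected_log2.index):
            raise DesignError("truth table labels and expectations disagree on genes")

    def genes_of(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


def _class_offsets(design: SimulationDesign) -> dict[str, dict[str, float]]:
    """Per-class log2 offset from baseline, per sample.

    * galactose_up_reversed: up in all six galactose arrays, still up under
      the ineffective monotherapies, back to baseline under the effective
      treatments (both combos and TH1834).
    * monotherapy_confounded: up in galactose but reduced by the single
      agents *and* their combos (so monotherapy subtraction is genuinely
      exercised); unaffected by TH1834.
    * temporal classes follow their Day-4/Day-6 trajectory; treated arrays
      sit at the Day-6 level (the treatments neither cause nor reverse these
      changes).
    * galactose_down_restored mirrors galactose_up_reversed downward.
    """
    e, s2 = design.galactose_effect, design.step2_effect
    d4 = GALACTOSE_SAMPLES[:3]
    d6 = GALACTOSE_SAMPLES[3:]

    def level(day4: float, day6: float, mono: float, combo: float, th: float):
        off = {CONTROL_SAMPLE: 0.0}
        off.update({s: day4 for s in d4})
        off.update({s: day6 for s in d6})
        off.update({s: mono for s in MONO_TREATMENTS})
        off.update({s: combo for s in COMBO_TREATMENTS})
        off["TH1834"] = th
        return off

    return {
        "galactose_up_reversed": level(e, e, e, 0.0, 0.0),
        "monotherapy_confounded": level(e, e, 0.0, 0.0, e),
        "early_plateau": level(e, e, e, e, e),
        "monotonic_rise": level(e, e + s2, e + s2, e + s2, e + s2),
        "early_peak": level(e, e - s2, e - s2, e - s2, e - s2),
        "late_rise": level(0.0, s2, s2, s2, s2),
        "galactose_down_restored": level(-e, -e, -e, 0.0, 0.0),
    }


def _sample_meta() -> pd.DataFrame:
    rows = {CONTROL_SAMPLE: ("control", pd.NA, pd.NA, 1)}
    for s in GALACTOSE_SAMPLES:
        day = 4 if "_d4_" in s else 6
        rows[s] = ("galactose", day, pd.NA, int(s[-1]))
    for s in TREATMENT_SAMPLES:
        rows[s] = ("treated", pd.NA, s, 1)
    meta = pd.DataFrame.from_dict(
        rows, orient="index", columns=["condition", "day", "treatment", "replicate"]
    )
    meta.index.name = "sample_id"
    return meta


def simulate_microarray(
    design: SimulationDesign,
) -> tuple[dict[str, ProbeLevelArray], SignalMatrix, TruthTable]:
    """Generate probe arrays, the derived signal matrix, and the truth table.

    The signal matrix value for a gene is the mean of its linear probe
    intensities on that array, matching how the pipeline's single-array
    contrasts summarise probes.
    """
    rng = np.random.default_rng(design.seed)
    genes = [f"G{i:05d}" for i in range(design.n_genes)]
    baseline = rng.normal(design.baseline_log2_mean, design.baseline_log2_sd, design.n_genes)

    labels = pd.Series("null", index=pd.Index(genes, name="gene_id"))
    pos = 0
    for cls in GENE_CLASSES:
        n = design.class_sizes.get(cls, 0)
        labels.iloc[pos : pos + n] = cls
        pos += n

    offsets = _class_offsets(design)
    mu = pd.DataFrame(0.0, index=labels.index, columns=list(ALL_SAMPLES))
    for cls, per_sample in offsets.items():
        idx = labels == cls
        for sample, off in per_sample.items():
            mu.loc[idx, sample] = off
    mu = mu.add(baseline, axis=0)

    arrays: dict[str, ProbeLevelArray] = {}
    signal = pd.DataFrame(index=labels.index, columns=list(ALL_SAMPLES), dtype=float)
    probe_cols = [f"probe_{j + 1}" for j in range(design.probes_per_gene)]
    for sample in ALL_SAMPLES:
        noise = rng.normal(0.0, design.probe_sd, size=(design.n_genes, design.probes_per_gene))
        intensities = np.exp2(mu[sample].to_numpy()[:, None] + noise)
        probes = pd.DataFrame(intensities, index=labels.index, columns=probe_cols)
        arrays[sample] = ProbeLevelArray(sample, probes)
        signal[sample] = intensities.mean(axis=1)

    matrix = SignalMatrix(signal, _sample_meta())
    truth = TruthTable(labels, mu)
    return arrays, matrix, truth


# ---------------------------------------------------------------------------
# lens images
# ---------------------------------------------------------------------------

def _disk_image(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    annulus_fraction: float,
    opacity: float,
    noise_sd: float,
    rng: np.random.Generator,
    background: float,
    disk_value: float,
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dist = np.hypot(yy - center[1], xx - center[0])
    img = np.full(shape, background, dtype=float)
    img[dist <= radius] = disk_value
    annulus = (dist <= radius) & (dist > (1.0 - annulus_fraction) * radius)
    img[annulus] += opacity
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def simulate_lens_images(
    radius: float = 80.0,
    annulus_fraction: float = 0.2,
    before_opacity: float = 20.0,
    after_opacity: float = 50.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    center: tuple[float, float] | None = None,
    background: float = 40.0,
    disk_value: float = 120.0,
):
    """Paired before/after 8-bit grayscale lens photographs.

    The lens is a bright disk on a dark background; the outer
    ``annulus_fraction`` of the disk radius (the cortical equator seen from
    above) carries the planted opacity increment on top of the disk value.
    Gaussian pixel noise is added then clipped to [0, 255].

    Returns ``(before, after, geometry)`` where geometry is a dict with
    ``center``, ``radius`` and ``annulus_fraction``.
    """
    if not 0 < annulus_fraction <= 1:
        raise DesignError("annulus_fraction must lie in (0, 1]")
    for opacity in (before_opacity, after_opacity):
        if not 0 <= opacity <= 255:
            raise DesignError("opacity must lie in [0, 255]")
    if center is None:
        center = (shape[1] / 2.0, shape[0] / 2.0)
    if radius <= 0 or radius > min(center[0], center[1], shape[1] - center[0], shape[0] - center[1]):
        raise DesignError("disk radius does not fit the canvas")
    rng = np.random.default_rng(seed)
    before = _disk_image(
        shape, center, radius, annulus_fraction, before_opacity, noise_sd, rng, background, disk_value
    )
    after = _disk_image(
        shape, center, radius, annulus_fraction, after_opacity, noise_sd, rng, background, disk_value
    )
    geometry = {"center": center, "radius": radius, "annulus_fraction": annulus_fraction}
    return before, after, geometry


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

QPCR_GROUPS = ("control", "galactose", "C646", "CBP30", "CPTH2", "C646+CPTH2", "CBP30+CPTH2", "TH1834")

#: which simulated arrays stand for each qPCR group
_GROUP_SAMPLES: dict[str, tuple[str, ...]] = {
    "control": (CONTROL_SAMPLE,),
    "galactose": GALACTOSE_SAMPLES,
    **{t: (t,) for t in TREATMENT_SAMPLES},
}


def planted_relative_expression(truth: TruthTable, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Planted gene × group relative expression (fold vs the control baseline)."""
    genes = list(genes) if genes is not None else list(truth.labels.index)
    base = truth.expected_log2.loc[genes, CONTROL_SAMPLE]
    out = {}
    for group, samples in _GROUP_SAMPLES.items():
        mean_log2 = truth.expected_log2.loc[genes, list(samples)].mean(axis=1)
        out[group] = np.exp2(mean_log2 - base)
    return pd.DataFrame(out, index=pd.Index(genes, name="gene_id"))


def simulate_qpcr(
    truth: TruthTable | pd.DataFrame,
    groups: Sequence[str] = QPCR_GROUPS,
    replicates: int = 3,
    ct_noise_sd: float = 0.15,
    seed: int = 0,
    genes: Sequence[str] | None = None,
    reference_ct: float = 18.0,
    target_base_ct: float = 24.0,
) -> pd.DataFrame:
    """Simulate a Ct table for a target panel normalised against Gapdh.

    ``truth`` is either a :class:`TruthTable` (relative expression is derived
    from the planted per-sample log2 means) or a gene × group DataFrame of
    planted relative expression values.  The model is

    ``Ct_target = target_base_ct − log2(relative expression) + noise``

    with the reference Ct constant in expectation across groups, so at zero
    noise ``2^(Ct_ref − Ct_target)`` recovers the planted expression up to one
    common factor, and group *ratios* are exact.
    """
    if isinstance(truth, TruthTable):
        expr = planted_relative_expression(truth, genes)
    else:
        expr = truth if genes is None else truth.loc[list(genes)]
    if replicates < 2:
        raise DesignError("need >= 2 replicates per group for testing")
    missing = [g for g in groups if g not in expr.columns]
    if missing:
        raise DesignError(f"groups without planted expression: {missing}")
    if (expr[list(groups)].to_numpy() <= 0).any():
        raise DesignError("planted relative expression must be positive")

    rng = np.random.default_rng(seed)
    rows = []
    for gene in expr.index:
        for group in groups:
            r = float(expr.loc[gene, group])
            for rep in range(1, replicates + 1):
                ct_ref = reference_ct + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                ct_tgt = target_base_ct - np.log2(r) + (
                    rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                )
                rows.append((gene, group, rep, ct_tgt, ct_ref))
    table = pd.DataFrame(rows, columns=["gene", "group", "replicate", "ct_target", "ct_reference"])
    # the scale convention: at zero noise 2^(ref - target) = r * 2^(ref - base)
    table.attrs["scale"] = 2.0 ** (reference_ct - target_base_ct)
    return table
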