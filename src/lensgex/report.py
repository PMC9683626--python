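"""End-to-end pipeline orchestration and descriptive ordination outputs.

``run_pipeline`` drives simulate → filter → screens → cascade → temporal →
report from one configuration and writes every stage's gene lists plus a
machine-readable run report whose counts are re-derivable from the emitted
files.  ``ordination_report`` produces the descriptive summaries used to eye
the sample structure: PCA coordinates and an average-linkage correlation
dendrogram on control-subtracted log2 signals of a selected gene set, plus
control-subtracted heatmap values (the control column is identically zero by
construction).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from . import __version__
from .cascade import ReversalCascade
from .errors import ConfigurationError
from .io import (
    CascadeConfig,
    GeneSet,
    SignalMatrix,
    write_gene_set,
    write_probe_array,
    write_signal_matrix,
)
from .simulate import SimulationDesign, simulate_microarray
from .temporal import TemporalMarkerModel

log = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Traceable record of one pipeline run."""

    config: dict
    seed: int
    stage_counts: dict[str, int]
    temporal_counts: dict[str, int]
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    log_lines: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "config": self.config,
                "stage_counts": self.stage_counts,
                "temporal_counts": self.temporal_counts,
                "outputs": self.outputs,
                "log": self.log_lines,
            },
            indent=2,
            sort_keys=True,
        )


def _design_from_config(sim_cfg: Mapping, seed: int) -> SimulationDesign:
    kwargs = dict(sim_cfg)
    kwargs.setdefault("seed", seed)
    known = set(SimulationDesign.__dataclass_fields__)
    unknown = set(kwargs) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
    return SimulationDesign(**kwargs)


def run_pipeline(
    config: Mapping | str | Path,
    outdir: str | Path,
    write_probes: bool = False,
) -> RunReport:
    """Execute the full pipeline from one configuration mapping or YAML path.

    The configuration may contain a ``simulate`` section (a
    :class:`SimulationDesign` field mapping), a ``cascade`` section (a
    :class:`CascadeConfig` field mapping), and a ``seed``.  Without a
    ``simulate`` section it must point to existing inputs via ``matrix`` (and
    optionally per-sample ``probes`` files).  Given the same seed the run is
    idempotent.
    """
    if not isinstance(config, Mapping):
        config = yaml.safe_load(Path(config).read_text()) or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    cascade_cfg = CascadeConfig(**config.get("cascade", {}))
    lines: list[str] = []
    outputs: list[str] = []

    def _emit(path: Path) -> None:
        outputs.append(str(path.relative_to(outdir)))

    if "simulate" in config:
        design = _design_from_config(config["simulate"], seed)
        lines.append(f"simulate: n_genes={design.n_genes} seed={design.seed}")
        probes, matrix, truth = simulate_microarray(design)
        write_signal_matrix(matrix, outdir / "signal_matrix.tsv")
        _emit(outdir / "signal_matrix.tsv")
        _emit(outdir / "signal_matrix.tsv.meta")
        truth_frame = truth.labels.to_frame("class")
        truth_frame.to_csv(outdir / "truth_table.tsv", sep="\t")
        _emit(outdir / "truth_table.tsv")
        if write_probes:
            probe_dir = outdir / "probes"
            probe_dir.mkdir(exist_ok=True)
            for sample, arr in probes.items():
                write_probe_array(arr, probe_dir / f"{sample.replace('+', '_')}.tsv")
                _emit(probe_dir / f"{sample.replace('+', '_')}.tsv")
    else:
        from .io import read_signal_matrix

        if "matrix" not in config:
            raise ConfigurationError("stage 'input': config needs 'simulate' or 'matrix'")
        matrix_path = Path(config["matrix"])
        if not matrix_path.exists():
            raise ConfigurationError(f"stage 'input': matrix file not found: {matrix_path}")
        matrix = read_signal_matrix(matrix_path, config.get("matrix_meta"))
        probes = None
        if "probes" in config:
            from .io import read_probe_array

            probes = {
                sample: read_probe_array(path, sample)
                for sample, path in config["probes"].items()
            }
        lines.append(f"input: {matrix_path} ({matrix.shape[0]} genes)")

    cascade = ReversalCascade(matrix, probes, cascade_cfg)
    results = cascade.fit()
    lines.append(f"cascade: {len(results.candidate_union)} candidate genes")

    sets_dir = outdir / "gene_sets"
    sets_dir.mkdir(exist_ok=True)

    def _write_set(s: GeneSet, stem: str) -> None:
        path = sets_dir / f"{stem}.txt"
        write_gene_set(s, path)
        _emit(path)

    for day, sets in results.replicate_sets.items():
        for s in sets:
            _write_set(s, f"day{day}_{s.name}")
        if day in results.replicate_intersections:
            _write_set(results.replicate_intersections[day], f"day{day}_intersection")
    for direction, by_alpha in results.reversal.items():
        for a, s in by_alpha.items():
            _write_set(s, f"reversal_{direction}_p{str(a).replace('.', '')}")
    for t, s in results.candidates.items():
        _write_set(s, f"candidates_{t.replace('+', '_')}")
    _write_set(results.candidate_union, "candidates_union")
    results.membership.to_csv(outdir / "candidate_membership.tsv", sep="\t")
    _emit(outdir / "candidate_membership.tsv")

    temporal = TemporalMarkerModel(
        results.filtered, cascade_cfg.temporal_fold, cascade_cfg.temporal_alpha
    ).fit()
    temporal.classification.to_csv(outdir / "temporal_classes.tsv", sep="\t")
    _emit(outdir / "temporal_classes.tsv")
    lines.append(
        "temporal: " + ", ".join(f"{c}={n}" for c, n in temporal.class_counts.items())
    )

    report = RunReport(
        config={k: v for k, v in config.items()},
        seed=seed,
        stage_counts=results.stage_counts,
        temporal_counts={c: int(n) for c, n in temporal.class_counts.items()},
        outputs=sorted(outputs),
        log_lines=lines,
    )
    (outdir / "run_report.json").write_text(report.to_json())
    return report


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def control_subtracted(matrix: SignalMatrix, gene_set: GeneSet | None = None,
                       log_scale: bool = False) -> pd.DataFrame:
    """Signals with the control column subtracted (zero for the control itself).

    ``log_scale`` subtracts on log2 signals instead of linear ones.
    """
    control = matrix.samples_where(condition="control")
    if len(control) != 1:
        raise ConfigurationError("control-subtraction needs exactly one control sample")
    values = matrix.log2() if log_scale else matrix.values
    if gene_set is not None:
        missing = gene_set.members - set(matrix.gene_ids)
        if missing:
            raise ConfigurationError(f"gene set members absent from matrix: {sorted(missing)[:5]}")
        values = values.loc[[g for g in values.index if g in gene_set.members]]
    return values.sub(values[control[0]], axis=0)


def ordination_report(
    matrix: SignalMatrix,
    gene_set: GeneSet | None = None,
    n_components: int = 2,
    outdir: str | Path | None = None,
) -> dict:
    """PCA, hierarchical clustering and heatmap values for a gene selection.

    PCA runs on control-subtracted log2 signals with samples as observations
    and genes as variables (gene-centered, SVD); clustering is average
    linkage on the (1 − Pearson) distance between samples.  Returns a dict
    with ``pca`` (sample × component DataFrame), ``explained_variance_ratio``,
    ``linkage`` (SciPy linkage matrix, or None for < 3 samples),
    ``sample_order`` and ``heatmap`` (control-subtracted linear signal
    values).  With ``outdir`` set, a heatmap PNG and the coordinate tables
    are also written.
    """
    if matrix.shape[1] < 2:
        raise ConfigurationError("ordination needs at least two samples")
    if gene_set is not None and len(gene_set) < 2:
        log.warning("ordination_report: singleton gene set, PCA skipped")
        return {"pca": None, "explained_variance_ratio": None, "linkage": None,
                "sample_order": matrix.sample_ids,
                "heatmap": control_subtracted(matrix, gene_set)}

    logdiff = control_subtracted(matrix, gene_set, log_scale=True)
    X = logdiff.to_numpy(dtype=float).T  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    total_var = (s ** 2).sum()
    evr = (s[:k] ** 2 / total_var) if total_var > 0 else np.zeros(k)
    pca = pd.DataFrame(
        coords, index=logdiff.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )

    link = None
    if X.shape[0] >= 3:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(X)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2
        link = linkage(squareform(dist, checks=False), method="average")

    heat = control_subtracted(matrix, gene_set, log_scale=False)
    out = {
        "pca": pca,
        "explained_variance_ratio": evr,
        "linkage": link,
        "sample_order": list(logdiff.columns),
        "heatmap": heat,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pca.to_csv(outdir / "pca_coordinates.tsv", sep="\t")
        heat.to_csv(outdir / "heatmap_values.tsv", sep="\t")
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 8))
        im = ax.imshow(heat.to_numpy(), aspect="auto", cmap="RdYlGn_r")
        ax.set_xticks(range(heat.shape[1]))
        ax.set_xticklabels(heat.columns, rotation=90, fontsize=6)
        ax.set_yticks([])
        ax.set_title("control-subtracted signal")
        fig.colorbar(im, ax=ax, shrink=0.5)
        fig.tight_layout()
        fig.savefig(outdir / "heatmap.png", dpi=120)
        plt.close(fig)
    return out
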