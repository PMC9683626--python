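"""Readers and writers for the pipeline's on-disk formats.

Four formats are supported, all plain text, all UTF-8:

* **signal matrix** — tab-separated, first column ``gene_id``, header row of
  sample ids, linear-scale non-negative signals; per-sample annotations live
  in a tab-separated *sidecar* file (``sample_id  condition  day  treatment
  replicate``) so the matrix itself stays minimal.
* **probe-level table** — tab-separated, one row per gene, columns
  ``probe_1 .. probe_k`` of per-array probe intensities.
* **gene list** — one gene id per line, with an optional ``#``-prefixed
  provenance header block (JSON payload) that survives round-trips.
* **GEO series matrix** — the line-oriented text convention used by NCBI GEO
  (``!``-prefixed metadata, a table delimited by ``!series_matrix_table_begin``
  / ``!series_matrix_table_end``); sample titles are mapped to annotations via
  a caller-supplied mapping.

Gene identifiers are opaque, case-sensitive strings; no symbol or alias
resolution is attempted.  Signals are linear on disk — log2 is computed
internally where needed and never persisted.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError

log = logging.getLogger(__name__)

CONDITIONS = ("control", "galactose", "treated")

#: linear-scale floor applied before any log2 transform
DEFAULT_EPSILON = 2.0 ** -10


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class SignalMatrix:
    """Gene × sample linear-scale expression signals with sample annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes as the index, samples as columns, non-negative linear signals.
    sample_meta : pandas.DataFrame
        Indexed by sample id with columns ``condition`` (control / galactose /
        treated), ``day`` (4, 6 or NA), ``treatment`` (label or NA) and
        ``replicate`` (int).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        if v.columns.has_duplicates:
            raise FormatError("duplicate sample ids in matrix header")
        if not all(np.issubdtype(dt, np.number) for dt in v.dtypes):
            raise FormatError("non-numeric cells in signal matrix")
        if (v.to_numpy() < 0).any():
            raise FormatError("negative signal values are not allowed")
        missing = [s for s in v.columns if s not in self.sample_meta.index]
        if missing:
            raise FormatError(f"samples without metadata: {missing}")
        for col in ("condition", "day", "treatment", "replicate"):
            if col not in self.sample_meta.columns:
                raise FormatError(f"sample metadata lacks column {col!r}")
        bad = set(self.sample_meta.loc[list(v.columns), "condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown conditions: {sorted(bad)}")

    # -- convenience -------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def meta_for(self, sample_id: str) -> pd.Series:
        return self.sample_meta.loc[sample_id]

    def samples_where(
        self,
        condition: str | None = None,
        day: int | None = None,
        treatment: str | None = None,
    ) -> list[str]:
        """Sample ids (matrix order) matching the given annotation filters."""
        keep = []
        for s in self.values.columns:
            m = self.sample_meta.loc[s]
            if condition is not None and m["condition"] != condition:
                continue
            if day is not None and not (pd.notna(m["day"]) and int(m["day"]) == day):
                continue
            if treatment is not None and m["treatment"] != treatment:
                continue
            keep.append(s)
        return keep

    def log2(self, epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
        """log2 of the signals with zeros floored at ``epsilon``."""
        return np.log2(self.values.clip(lower=epsilon))

    def subset_genes(self, genes: Iterable[str]) -> "SignalMatrix":
        wanted = set(genes)
        keep = [g for g in self.values.index if g in wanted]
        return SignalMatrix(self.values.loc[keep], self.sample_meta)


@dataclass
class ProbeLevelArray:
    """Per-sample probe intensities grouped by gene.

    ``probes`` is a DataFrame (genes × probe columns); ragged probe counts are
    represented by trailing NaN, but every gene must carry at least two finite
    probes — that replication is the only within-pair variance source for the
    single-array contrasts.
    """

    sample_id: str
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.probes.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if (finite.sum(axis=1) < 2).any():
            bad = self.probes.index[finite.sum(axis=1) < 2].tolist()
            raise FormatError(f"genes with <2 probes in {self.sample_id}: {bad[:5]}")
        if (vals[finite] < 0).any():
            raise FormatError(f"negative probe intensity in {self.sample_id}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.probes.index)

    def gene_probes(self, gene: str) -> np.ndarray:
        row = self.probes.loc[gene].to_numpy(dtype=float)
        return row[np.isfinite(row)]


@dataclass
class GeneSet:
    """A named set of gene identifiers with a filter provenance trail.

    ``provenance`` is an ordered list of descriptors, each a dict with at
    least ``operation`` and ``params`` keys, recording the filters that
    produced the set.  Derived sets must carry a non-empty trail.
    """

    name: str
    members: frozenset[str]
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(sorted(self.members))

    def derive(self, name: str, members: Iterable[str], step: dict) -> "GeneSet":
        return GeneSet(name, frozenset(members), self.provenance + [step])


@dataclass
class CascadeConfig:
    """Thresholds and group structure of the candidate-extraction cascade.

    Defaults mirror the study design: linear-signal cutoff 5 for the
    low-signal filter, raw P thresholds 0.1 / 0.05 / 0.01 (no multiple-testing
    correction anywhere), 1.5-fold for the temporal steps, a 2-fold gate for
    the TH1834 branch, and the three treatments with a therapeutic effect.
    """

    low_signal_cutoff: float = 5.0
    alpha: float = 0.1
    alpha_levels: tuple[float, ...] = (0.1, 0.05, 0.01)
    temporal_fold: float = 1.5
    temporal_alpha: float = 0.05
    th1834_fold: float = 2.0
    effective_treatments: tuple[str, ...] = ("C646+CPTH2", "CBP30+CPTH2", "TH1834")
    combo_components: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "C646+CPTH2": ("C646", "CPTH2"),
            "CBP30+CPTH2": ("CBP30", "CPTH2"),
        }
    )
    #: galactose-up qualification in the median screen: how many of the six
    #: galactose arrays must individually exceed the control (probe mode)
    median_min_up: int = 4
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        for a in (self.alpha, *self.alpha_levels):
            if not 0 < a < 1:
                raise ConfigurationError(f"alpha {a} outside (0, 1)")
        for f in (self.temporal_fold, self.th1834_fold):
            if f <= 1:
                raise ConfigurationError(f"fold threshold {f} must exceed 1")
        if self.low_signal_cutoff < 0:
            raise ConfigurationError("low_signal_cutoff must be >= 0")
        for combo, monos in self.combo_components.items():
            if len(monos) < 1:
                raise ConfigurationError(f"combo {combo} maps to no monotherapies")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CascadeConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "combo_components" in raw:
            raw["combo_components"] = {
                k: tuple(v) for k, v in raw["combo_components"].items()
            }
        for key in ("alpha_levels", "effective_treatments"):
            if key in raw:
                raw[key] = tuple(raw[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "low_signal_cutoff": self.low_signal_cutoff,
            "alpha": self.alpha,
            "alpha_levels": list(self.alpha_levels),
            "temporal_fold": self.temporal_fold,
            "temporal_alpha": self.temporal_alpha,
            "th1834_fold": self.th1834_fold,
            "effective_treatments": list(self.effective_treatments),
            "combo_components": {k: list(v) for k, v in self.combo_components.items()},
            "median_min_up": self.median_min_up,
            "epsilon": self.epsilon,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# signal matrix I/O
# ---------------------------------------------------------------------------

def _default_meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta")


def _parse_day(x: str):
    if x in ("", "NA", "NaN", "nan", "None"):
        return pd.NA
    return int(float(x))


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated sample annotation sidecar."""
    path = Path(path)
    rows = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[0] != "sample_id":
            raise FormatError(f"{path}: sidecar must start with a sample_id header")
        expected = ["sample_id", "condition", "day", "treatment", "replicate"]
        if header != expected:
            raise FormatError(f"{path}: sidecar header must be {expected}, got {header}")
        for line in reader:
            if not line or not any(line):
                continue
            sid, condition, day, treatment, replicate = line
            if sid in rows:
                raise FormatError(f"{path}: duplicate sample id {sid!r}")
            rows[sid] = {
                "condition": condition,
                "day": _parse_day(day),
                "treatment": treatment if treatment not in ("", "NA") else pd.NA,
                "replicate": int(replicate),
            }
    meta = pd.DataFrame.from_dict(rows, orient="index")
    meta.index.name = "sample_id"
    return meta


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "condition", "day", "treatment", "replicate"])
        for sid, m in meta.iterrows():
            day = "" if pd.isna(m["day"]) else int(m["day"])
            treatment = "" if pd.isna(m["treatment"]) else m["treatment"]
            w.writerow([sid, m["condition"], day, treatment, int(m["replicate"])])


def read_signal_matrix(path: str | Path, meta_path: str | Path | None = None) -> SignalMatrix:
    """Read a tab-separated signal matrix plus its annotation sidecar.

    The first column holds gene ids and the header row sample ids.  Cells must
    be non-negative decimal numbers (decimal point only; thousands separators
    are a format error, not silently accepted).
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _default_meta_path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse matrix: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene row(s): {dupes}")
    values = pd.DataFrame(index=df.index.astype(str), columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            values[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric cell in sample {col!r}: {exc}") from exc
    if (values.to_numpy() < 0).any():
        gene = values.index[(values < 0).any(axis=1)][0]
        raise FormatError(f"{path}: negative signal for gene {gene!r}")
    if not meta_path.exists():
        raise FormatError(f"metadata sidecar not found: {meta_path}")
    meta = read_sample_meta(meta_path)
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise FormatError(f"{path}: missing metadata for sample(s) {missing}")
    return SignalMatrix(values, meta)


def write_signal_matrix(
    matrix: SignalMatrix, path: str | Path, meta_path: str | Path | None = None
) -> None:
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _default_meta_path(path)
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")
    write_sample_meta(matrix.sample_meta.loc[list(matrix.values.columns)], meta_path)


# ---------------------------------------------------------------------------
# probe-level I/O
# ---------------------------------------------------------------------------

def read_probe_array(path: str | Path, sample_id: str | None = None) -> ProbeLevelArray:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene rows")
    return ProbeLevelArray(sample_id or path.stem, df.astype(float))


def write_probe_array(array: ProbeLevelArray, path: str | Path) -> None:
    out = array.probes.copy()
    out.index.name = "gene_id"
    out.to_csv(Path(path), sep="\t", lineterminator="\n", float_format="%.10g")


# ---------------------------------------------------------------------------
# gene list I/O
# ---------------------------------------------------------------------------

_PROV_PREFIX = "#provenance "
_NAME_PREFIX = "#name "


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a plain-text gene list (one id per line, optional header block).

    Duplicated ids collapse to one membership (set semantics); the collapse is
    logged.  An empty file yields an empty set with a warning, not an error.
    """
    path = Path(path)
    members: list[str] = []
    provenance: list[dict] = []
    set_name = name or path.stem
    for line in path.read_text().splitlines():
        if line.startswith(_PROV_PREFIX):
            provenance.append(json.loads(line[len(_PROV_PREFIX):]))
        elif line.startswith(_NAME_PREFIX):
            if name is None:
                set_name = line[len(_NAME_PREFIX):].strip()
        elif line.startswith("#") or not line.strip():
            continue
        else:
            members.append(line.strip())
    unique = frozenset(members)
    if len(unique) < len(members):
        log.info("%s: %d duplicate ids collapsed", path, len(members) - len(unique))
    if not unique:
        log.warning("%s: empty gene list", path)
    return GeneSet(set_name, unique, provenance)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    lines = [f"{_NAME_PREFIX}{gene_set.name}"]
    lines += [f"{_PROV_PREFIX}{json.dumps(step, sort_keys=True)}" for step in gene_set.provenance]
    lines += sorted(gene_set.members)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GEO series-matrix format
# ---------------------------------------------------------------------------

def _split_geo_line(line: str) -> list[str]:
    """Split a GEO series-matrix line on tabs, stripping optional quotes."""
    fields = next(csv.reader([line], delimiter="\t", quotechar='"'))
    return fields


def read_geo_series_matrix(
    path: str | Path,
    sample_meta: Mapping[str, Mapping] | pd.DataFrame,
) -> SignalMatrix:
    """Parse a GEO series-matrix text file into a :class:`SignalMatrix`.

    ``sample_meta`` maps sample *titles* (as given on the ``!Sample_title``
    line; sample accessions are accepted as a fallback) to annotation records
    with keys ``condition``, ``day``, ``treatment``, ``replicate``.  Every
    sample in the table must be mapped.
    """
    path = Path(path)
    titles: list[str] | None = None
    accessions: list[str] | None = None
    table_lines: list[list[str]] = []
    in_table = False
    saw_begin = saw_end = False
    for line in path.read_text().splitlines():
        if line.startswith("!series_matrix_table_begin"):
            in_table, saw_begin = True, True
            continue
        if line.startswith("!series_matrix_table_end"):
            in_table, saw_end = False, True
            continue
        if in_table:
            if line.strip():
                table_lines.append(_split_geo_line(line))
        elif line.startswith("!Sample_title"):
            titles = _split_geo_line(line)[1:]
        elif line.startswith("!Sample_geo_accession"):
            accessions = _split_geo_line(line)[1:]
    if not saw_begin or not saw_end:
        raise FormatError(f"{path}: series-matrix table markers not found")
    if not table_lines:
        raise FormatError(f"{path}: empty series-matrix table")

    header = table_lines[0]
    sample_cols = header[1:]
    # prefer titles for naming; fall back to table header / accessions
    if titles is not None and len(titles) == len(sample_cols):
        names = titles
    else:
        names = sample_cols

    if isinstance(sample_meta, pd.DataFrame):
        mapping = {str(k): v for k, v in sample_meta.to_dict(orient="index").items()}
    else:
        mapping = {str(k): dict(v) for k, v in sample_meta.items()}

    meta_rows = {}
    for i, title in enumerate(names):
        rec = mapping.get(title)
        if rec is None and accessions is not None and i < len(accessions):
            rec = mapping.get(accessions[i])
        if rec is None and names is not sample_cols:
            rec = mapping.get(sample_cols[i])
        if rec is None:
            raise ConfigurationError(f"{path}: sample title {title!r} has no metadata mapping")
        meta_rows[title] = {
            "condition": rec["condition"],
            "day": rec.get("day", pd.NA),
            "treatment": rec.get("treatment", pd.NA),
            "replicate": int(rec.get("replicate", 1)),
        }

    genes, data = [], []
    for row in table_lines[1:]:
        genes.append(row[0])
        try:
            data.append([float(x) if x not in ("", "null", "NA") else math.nan for x in row[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell in row {row[0]!r}") from exc
    values = pd.DataFrame(data, index=genes, columns=names, dtype=float)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "sample_id"
    meta["day"] = meta["day"].astype("object")
    return SignalMatrix(values, meta)
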