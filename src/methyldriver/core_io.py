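"""Shared data containers and delimited-text I/O.

Beta-value methylation matrices, log-scale expression matrices, sample
metadata, probe-to-gene annotation, probe-cluster definitions and GMT gene
sets, together with the preprocessing steps every downstream stage relies
on: NA-probe removal, PCA outlier screening, and probe -> cluster -> gene
aggregation of beta values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TISSUE_CLASSES = ("normal", "adjacent", "adenoma_low", "adenoma_high", "cancer", "cfdna")
STAGES = ("none", "0", "I", "II", "III", "IV")

#: tokens parsed as a missing beta/expression value (R and spreadsheet exports)
MISSING_TOKENS = ("NA", "NaN", "nan", "")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class MethylationMatrix:
    """Feature x sample matrix of beta values in [0, 1] (NaN = missing).

    Features are probes at input, and cluster or gene identifiers after
    aggregation; the container and its invariants are identical at every
    level.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(list(self.data.index), "feature ID")
        _check_unique(list(self.data.columns), "sample ID")
        v = self.data.to_numpy()
        bad = (v < 0) | (v > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value out of [0, 1] at feature {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}: {v[i, j]}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    # probes are just features at the first aggregation level
    probe_ids = feature_ids

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log-scale expression (any real value)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(list(self.data.index), "gene ID")
        _check_unique(list(self.data.columns), "sample ID")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SampleMetadata:
    """Per-sample tissue class, stage and cohort label.

    ``data`` is indexed by sample ID with columns ``tissue_class``,
    ``stage`` and ``cohort``.  ``stage`` may differ from ``"none"`` only for
    cancer tissue and cfDNA samples.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "sample ID")
        for col in ("tissue_class", "stage"):
            if col not in self.data.columns:
                raise ValueError(f"metadata missing column {col!r}")
        if "cohort" not in self.data.columns:
            self.data = self.data.assign(cohort="")
        bad_cls = set(self.data["tissue_class"]) - set(TISSUE_CLASSES)
        if bad_cls:
            raise ValueError(f"unknown tissue_class values: {sorted(bad_cls)}")
        bad_stage = set(self.data["stage"].astype(str)) - set(STAGES)
        if bad_stage:
            raise ValueError(f"unknown stage values: {sorted(bad_stage)}")
        self.data["stage"] = self.data["stage"].astype(str)
        staged = self.data["stage"] != "none"
        allowed = self.data["tissue_class"].isin(["cancer", "cfdna"])
        if (staged & ~allowed).any():
            sid = self.data.index[staged & ~allowed][0]
            raise ValueError(f"sample {sid!r} has a stage but is not cancer/cfdna")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def tissue_class(self) -> pd.Series:
        return self.data["tissue_class"]

    def stage(self) -> pd.Series:
        return self.data["stage"]

    def samples_of(self, *classes: str) -> list[str]:
        return list(self.data.index[self.data["tissue_class"].isin(classes)])


@dataclass
class ProbeAnnotation:
    """Many-to-one mapping of probe ID to gene symbol."""

    mapping: pd.Series  # index = probe_id, values = gene symbol

    def __post_init__(self) -> None:
        _check_unique(list(self.mapping.index), "probe ID")
        self.mapping = self.mapping.astype(str)

    def gene_of(self, probe_id: str) -> str:
        return str(self.mapping[probe_id])

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.mapping.index

    @property
    def genes(self) -> list[str]:
        # preserves probe order of first appearance
        return list(dict.fromkeys(self.mapping))


@dataclass(frozen=True)
class ClusterDefinition:
    """A named group of correlated probes within one gene."""

    cluster_id: str
    gene: str
    probe_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValueError(f"cluster {self.cluster_id!r} has no member probes")


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.sets], "gene set name")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


# ---------------------------------------------------------------------------
# delimited-text readers / writers
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_matrix(path: str | Path, kind: str) -> MethylationMatrix | ExpressionMatrix:
    """Read a feature x sample matrix from TSV/CSV.

    First column holds feature IDs, header row holds sample IDs.  ``kind``
    selects validation: ``"methylation"`` enforces beta values in [0, 1],
    ``"expression"`` accepts any real.  Cells equal to one of
    :data:`MISSING_TOKENS` parse as missing.
    """
    path = Path(path)
    if kind not in ("methylation", "expression"):
        raise ValueError(f"kind must be 'methylation' or 'expression', got {kind!r}")
    sep = _sniff_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    _check_unique(header[1:], "sample ID")
    df = pd.read_csv(
        path, sep=sep, index_col=0,
        na_values=list(MISSING_TOKENS), keep_default_na=False,
    )
    df.index = df.index.astype(str)
    _check_unique(list(df.index), "feature ID")
    if kind == "methylation":
        return MethylationMatrix(df)
    return ExpressionMatrix(df)


def write_matrix(m: MethylationMatrix | ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix; lossless round-trip with :func:`read_matrix`."""
    m.data.to_csv(path, sep=sep, na_rep="NA")


def read_metadata(path: str | Path) -> SampleMetadata:
    sep = _sniff_sep(Path(path))
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path, sep: str = "\t") -> None:
    meta.data.to_csv(path, sep=sep, index_label="sample_id")


def read_annotation(path: str | Path) -> ProbeAnnotation:
    sep = _sniff_sep(Path(path))
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return ProbeAnnotation(pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values))


def write_annotation(annot: ProbeAnnotation, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame({"probe_id": annot.mapping.index, "gene": annot.mapping.values}).to_csv(
        path, sep=sep, index=False
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description, members."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            sets.append(GeneSet(fields[0], fields[1], tuple(fields[2:])))
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in coll:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def drop_na_probes(m: MethylationMatrix) -> MethylationMatrix:
    """Remove every probe containing at least one missing value."""
    keep = ~m.data.isna().any(axis=1)
    if not keep.any():
        raise ValueError("no complete probes")
    return MethylationMatrix(m.data.loc[keep])


def pca_outlier_screen(
    m: MethylationMatrix, k_sd: float = 3.0
) -> tuple[list[str], list[str]]:
    """Flag samples whose PC1/PC2 score is an outlier.

    Covariance PCA on centered sample profiles; a sample is flagged when its
    score on either of the first two components lies strictly more than
    ``k_sd`` standard deviations from that component's mean.
    """
    if m.data.shape[1] < 3:
        raise ValueError("pca_outlier_screen requires at least 3 samples")
    if m.data.isna().any().any():
        raise ValueError("pca_outlier_screen requires complete data; drop NA probes first")
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    samples = m.sample_ids
    if not np.isfinite(k_sd):
        return samples, []
    X = m.values.T  # samples x probes
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    n_comp = min(2, len(s))
    scores = u[:, :n_comp] * s[:n_comp]
    flagged_mask = np.zeros(len(samples), dtype=bool)
    for c in range(n_comp):
        sc = scores[:, c]
        sd = sc.std()
        flagged_mask |= np.abs(sc - sc.mean()) > k_sd * sd
    flagged = [sid for sid, f in zip(samples, flagged_mask) if f]
    kept = [sid for sid, f in zip(samples, flagged_mask) if not f]
    return kept, flagged


def aggregate_clusters(
    m: MethylationMatrix, defs: Iterable[ClusterDefinition]
) -> MethylationMatrix:
    """Cluster-level beta = arithmetic mean of member-probe betas per sample."""
    defs = list(defs)
    _check_unique([d.cluster_id for d in defs], "cluster ID")
    index = {p: i for i, p in enumerate(m.feature_ids)}
    rows = []
    for d in defs:
        idx = []
        for p in d.probe_ids:
            if p not in index:
                raise ValueError(f"cluster {d.cluster_id!r} references absent probe {p!r}")
            idx.append(index[p])
        sub = m.values[idx]
        if np.isnan(sub).any():
            raise ValueError(f"cluster {d.cluster_id!r} has missing member-probe values")
        rows.append(sub.mean(axis=0))
    return MethylationMatrix(
        pd.DataFrame(rows, index=[d.cluster_id for d in defs], columns=m.sample_ids)
    )


def gene_level_methylation(
    m: MethylationMatrix, defs: Iterable[ClusterDefinition]
) -> MethylationMatrix:
    """Gene-level beta = mean over the gene's cluster-level betas per sample."""
    defs = list(defs)
    by_gene: dict[str, list[str]] = {}
    for d in defs:
        by_gene.setdefault(d.gene, []).append(d.cluster_id)
    index = {c: i for i, c in enumerate(m.feature_ids)}
    rows = []
    for gene, cluster_ids in by_gene.items():
        for c in cluster_ids:
            if c not in index:
                raise ValueError(f"gene {gene!r} references absent cluster {c!r}")
        rows.append(m.values[[index[c] for c in cluster_ids]].mean(axis=0))
    return MethylationMatrix(
        pd.DataFrame(rows, index=list(by_gene), columns=m.sample_ids)
    )
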