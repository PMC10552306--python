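"""Gene-centric mutational-load encoding of annotated exome variants.

Each whole-exome sample is summarised as a ``genes x functional-classes``
histogram of variant counts ("mutational load"): for every gene we count how
many variants of each functional class map to it.  Stacking samples yields an
``n x |G| x C`` tensor, the input representation shared by every model in this
package.  This module also carries the pathway-membership (GMT) and gene-gene
edge resources used to sparsify network layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "VocabularyError",
    "ClassVocabulary",
    "CLASSES_17",
    "DEFAULT_CLASSES_16",
    "AnnotatedVariantTable",
    "StandardizationStats",
    "GeneCentricTensor",
    "PathwayMap",
    "GeneGeneEdges",
    "DUMMY_PATHWAY",
    "read_variant_table",
    "encode_gene_centric",
    "standardize",
    "inverse_standardize",
    "read_gmt",
    "read_gene_edges",
]


class SchemaError(ValueError):
    """A tabular input does not have the expected columns."""


class VocabularyError(ValueError):
    """A value falls outside the configured vocabulary."""


# The Annovar-style functional classes.  The canonical printed list has 17
# names; the shipped default merges the two rare translation-boundary classes
# (stoploss/startloss) into one so that the histogram is 16-dimensional.
CLASSES_17: tuple[str, ...] = (
    "UTR3",
    "UTR5",
    "splicing",
    "upstream",
    "downstream",
    "intronic",
    "intronic ncRNA",
    "exonic ncRNA",
    "splicing ncRNA",
    "exonic non-frameshift insertion",
    "exonic frameshift insertion",
    "exonic non-frameshift deletion",
    "exonic frameshift deletion",
    "exonic stoploss",
    "exonic stopgain",
    "exonic startloss",
    "exonic nonsynonymous",
)


@dataclass(frozen=True)
class ClassVocabulary:
    """Ordered vocabulary of variant functional classes.

    ``aliases`` maps out-of-vocabulary input names onto canonical classes
    (used by the default 16-class vocabulary to fold "exonic startloss" into
    the merged stop/start-loss class).
    """

    classes: tuple[str, ...]
    aliases: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.classes) < 1:
            raise ValueError("vocabulary must contain at least one class")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("class names must be unique")

    @property
    def size(self) -> int:
        return len(self.classes)

    def index_of(self, name: str) -> int:
        name = self.aliases.get(name, name)
        try:
            return self.classes.index(name)
        except ValueError:
            raise VocabularyError(f"unknown functional class: {name!r}") from None

    def canonical(self, name: str) -> str:
        return self.aliases.get(name, name)


DEFAULT_CLASSES_16 = ClassVocabulary(
    classes=tuple(
        c for c in CLASSES_17 if c not in ("exonic stoploss", "exonic startloss")
    )
    + ("exonic stoploss/startloss",),
    aliases={
        "exonic stoploss": "exonic stoploss/startloss",
        "exonic startloss": "exonic stoploss/startloss",
    },
)

VOCAB_17 = ClassVocabulary(classes=CLASSES_17)


@dataclass
class AnnotatedVariantTable:
    """Long-format annotated variants: one row per (sample, gene, class).

    Backed by a pandas DataFrame with columns ``sample_id``, ``gene_id``,
    ``functional_class``; a triple may repeat (multiple variants of the same
    class on the same gene).
    """

    frame: pd.DataFrame
    vocab: ClassVocabulary

    def __post_init__(self) -> None:
        required = {"sample_id", "gene_id", "functional_class"}
        missing = required - set(self.frame.columns)
        if missing:
            raise SchemaError(f"variant table missing columns: {sorted(missing)}")

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, str]],
        vocab: ClassVocabulary,
    ) -> "AnnotatedVariantTable":
        frame = pd.DataFrame(
            list(records), columns=["sample_id", "gene_id", "functional_class"]
        )
        return cls._validated(frame, vocab)

    @classmethod
    def _validated(cls, frame: pd.DataFrame, vocab: ClassVocabulary) -> "AnnotatedVariantTable":
        if len(frame):
            frame = frame.copy()
            frame["functional_class"] = frame["functional_class"].map(
                lambda c: vocab.aliases.get(c, c)
            )
            seen = set(frame["functional_class"].unique())
            unknown = sorted(seen - set(vocab.classes))
            if unknown:
                raise VocabularyError(
                    f"functional classes not in vocabulary: {unknown}"
                )
        return cls(frame=frame, vocab=vocab)

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> Iterator[tuple[str, str, str]]:
        return iter(
            self.frame[["sample_id", "gene_id", "functional_class"]].itertuples(
                index=False, name=None
            )
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.frame["sample_id"]))

    @property
    def gene_ids(self) -> list[str]:
        return list(pd.unique(self.frame["gene_id"]))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path, vocab: ClassVocabulary) -> AnnotatedVariantTable:
    """Read a TSV with header ``sample_id  gene_id  functional_class``."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "gene_id", "functional_class"} - set(frame.columns)
    if missing:
        raise SchemaError(
            f"variant table {path} missing columns: {sorted(missing)}"
        )
    return AnnotatedVariantTable._validated(frame, vocab)


@dataclass(frozen=True)
class StandardizationStats:
    """Per-class (or per gene-class) moments used to z-score count tensors."""

    mode: str  # "per_class" or "per_gene_class"
    mean: np.ndarray  # (C,) or (G, C)
    sd: np.ndarray
    classes: tuple[str, ...]
    gene_ids: tuple[str, ...] | None = None


@dataclass
class GeneCentricTensor:
    """``n_samples x n_genes x C`` mutational-load counts.

    Before standardization every entry is a non-negative integer count; after
    :func:`standardize` the entries are z-scores and ``stats`` records the
    moments so the transform can be inverted.
    """

    counts: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    vocab: ClassVocabulary
    standardized: bool = False
    stats: StandardizationStats | None = None

    def __post_init__(self) -> None:
        n, g, c = self.counts.shape
        if n != len(self.sample_ids) or g != len(self.gene_ids) or c != self.vocab.size:
            raise ValueError("tensor shape inconsistent with vocabularies")
        if not self.standardized:
            if np.any(self.counts < 0):
                raise ValueError("raw counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def save(self, path: str | Path) -> None:
        """Persist as a compressed array plus a JSON sidecar."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), counts=self.counts)
        meta = {
            "sample_ids": self.sample_ids,
            "gene_ids": self.gene_ids,
            "classes": list(self.vocab.classes),
            "aliases": self.vocab.aliases,
            "standardized": self.standardized,
        }
        if self.stats is not None:
            meta["stats"] = {
                "mode": self.stats.mode,
                "mean": self.stats.mean.tolist(),
                "sd": self.stats.sd.tolist(),
            }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "GeneCentricTensor":
        path = Path(path)
        counts = np.load(path.with_suffix(".npz"))["counts"]
        meta = json.loads(path.with_suffix(".json").read_text())
        vocab = ClassVocabulary(tuple(meta["classes"]), meta.get("aliases", {}))
        stats = None
        if "stats" in meta:
            stats = StandardizationStats(
                mode=meta["stats"]["mode"],
                mean=np.asarray(meta["stats"]["mean"]),
                sd=np.asarray(meta["stats"]["sd"]),
                classes=vocab.classes,
            )
        return cls(
            counts=counts,
            sample_ids=meta["sample_ids"],
            gene_ids=meta["gene_ids"],
            vocab=vocab,
            standardized=meta["standardized"],
            stats=stats,
        )


def encode_gene_centric(
    table: AnnotatedVariantTable,
    genes: Sequence[str],
    vocab: ClassVocabulary,
    *,
    sample_ids: Sequence[str] | None = None,
    drop_unknown_genes: bool = False,
) -> GeneCentricTensor:
    """Count, per (sample, gene), variants of each functional class.

    ``sample_ids`` fixes the sample axis (samples with no variant records get
    all-zero slices); when omitted it is the order of first appearance in the
    table.
    """
    genes = list(genes)
    if sample_ids is None:
        sample_ids = table.sample_ids
    sample_ids = list(sample_ids)

    gene_index = {g: i for i, g in enumerate(genes)}
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    n, g_count, c_count = len(sample_ids), len(genes), vocab.size
    counts = np.zeros((n, g_count, c_count), dtype=np.int64)

    if table.n_records:
        frame = table.frame
        unknown_genes = set(frame["gene_id"].unique()) - set(genes)
        if unknown_genes and not drop_unknown_genes:
            raise VocabularyError(
                f"genes not in vocabulary: {sorted(unknown_genes)[:10]}"
            )
        if unknown_genes:
            frame = frame[frame["gene_id"].isin(gene_index)]
        unknown_samples = set(frame["sample_id"].unique()) - set(sample_index)
        if unknown_samples:
            raise VocabularyError(
                f"samples not in the configured sample list: {sorted(unknown_samples)[:10]}"
            )
        s = frame["sample_id"].map(sample_index).to_numpy()
        g = frame["gene_id"].map(gene_index).to_numpy()
        c = frame["functional_class"].map(
            {name: i for i, name in enumerate(vocab.classes)}
        ).to_numpy()
        np.add.at(counts, (s, g, c), 1)

    return GeneCentricTensor(
        counts=counts, sample_ids=sample_ids, gene_ids=genes, vocab=vocab
    )


def fit_standardization_stats(
    counts: np.ndarray, vocab: ClassVocabulary, mode: str = "per_class",
    gene_ids: Sequence[str] | None = None,
) -> StandardizationStats:
    """Moments pooled per functional class (across genes and samples), or per
    (gene, class) when ``mode="per_gene_class"``."""
    if mode == "per_class":
        flat = counts.reshape(-1, counts.shape[2]).astype(np.float64)
        mean = flat.mean(axis=0)
        sd = flat.std(axis=0, ddof=0)
    elif mode == "per_gene_class":
        mean = counts.mean(axis=0)
        sd = counts.std(axis=0, ddof=0)
    else:
        raise ValueError(f"unknown standardization mode: {mode!r}")
    return StandardizationStats(
        mode=mode, mean=mean, sd=sd, classes=vocab.classes,
        gene_ids=tuple(gene_ids) if gene_ids is not None else None,
    )


def standardize(
    tensor: GeneCentricTensor,
    fit_stats: StandardizationStats | None = None,
    mode: str = "per_class",
) -> GeneCentricTensor:
    """Z-score counts; moments pooled per class across genes and samples.

    When ``fit_stats`` is given (test-set use) they are applied as-is, so the
    transform never leaks test-set information.  Features with zero training
    variance map to 0.
    """
    if tensor.standardized:
        raise ValueError("tensor is already standardized")
    if fit_stats is None:
        fit_stats = fit_standardization_stats(
            tensor.counts, tensor.vocab, mode, tensor.gene_ids
        )
    else:
        if tuple(fit_stats.classes) != tuple(tensor.vocab.classes):
            raise VocabularyError("standardization stats use a different class vocabulary")
        if fit_stats.mode == "per_gene_class" and fit_stats.gene_ids is not None:
            if tuple(fit_stats.gene_ids) != tuple(tensor.gene_ids):
                raise VocabularyError("standardization stats use a different gene vocabulary")
    sd_safe = np.where(fit_stats.sd > 0, fit_stats.sd, 1.0)
    z = (tensor.counts.astype(np.float64) - fit_stats.mean) / sd_safe
    z = np.where(fit_stats.sd > 0, z, 0.0)
    return GeneCentricTensor(
        counts=z,
        sample_ids=tensor.sample_ids,
        gene_ids=tensor.gene_ids,
        vocab=tensor.vocab,
        standardized=True,
        stats=fit_stats,
    )


def inverse_standardize(tensor: GeneCentricTensor) -> GeneCentricTensor:
    """Undo :func:`standardize`; exact for features with sd > 0."""
    if not tensor.standardized or tensor.stats is None:
        raise ValueError("tensor is not standardized")
    st = tensor.stats
    raw = tensor.counts.astype(np.float64) * st.sd + st.mean
    return GeneCentricTensor(
        counts=raw,
        sample_ids=tensor.sample_ids,
        gene_ids=tensor.gene_ids,
        vocab=tensor.vocab,
        standardized=True,  # not integer counts; flag prevents re-standardizing stats-free
        stats=None,
    )


DUMMY_PATHWAY = "__dummy__"


@dataclass
class PathwayMap:
    """Gene -> pathway memberships, with a single shared dummy pathway for
    genes that belong to no annotated pathway."""

    memberships: dict
    pathway_ids: list[str]
    dummy_id: str = DUMMY_PATHWAY
    finalized: bool = False

    def finalize(self, genes: Sequence[str]) -> "PathwayMap":
        """Restrict to ``genes`` and route orphans to the dummy pathway."""
        memberships = {}
        used: set[str] = set()
        for g in genes:
            m = set(self.memberships.get(g, ())) & set(self.pathway_ids)
            if not m:
                m = {self.dummy_id}
            memberships[g] = frozenset(m)
            used |= m
        ordered = [p for p in self.pathway_ids if p in used]
        if self.dummy_id in used:
            ordered.append(self.dummy_id)
        return PathwayMap(
            memberships=memberships,
            pathway_ids=ordered,
            dummy_id=self.dummy_id,
            finalized=True,
        )

    def pathways_of(self, gene: str) -> frozenset:
        return frozenset(self.memberships.get(gene, ()))


def read_gmt(path: str | Path) -> PathwayMap:
    """Parse a GMT file (set name, description, tab-separated gene ids)."""
    memberships: dict = {}
    pathway_ids: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise SchemaError(f"malformed GMT line: {line[:80]!r}")
        name = parts[0]
        if name in seen:
            raise SchemaError(f"duplicate pathway name in GMT: {name!r}")
        seen.add(name)
        pathway_ids.append(name)
        for gene in parts[2:]:
            if gene:
                memberships.setdefault(gene, set()).add(name)
    return PathwayMap(
        memberships={g: frozenset(m) for g, m in memberships.items()},
        pathway_ids=pathway_ids,
    )


def write_gmt(pm: PathwayMap, path: str | Path) -> None:
    inverted: dict = {p: [] for p in pm.pathway_ids if p != pm.dummy_id}
    for gene, paths in pm.memberships.items():
        for p in paths:
            if p in inverted:
                inverted[p].append(gene)
    lines = [
        "\t".join([p, "na"] + sorted(genes)) for p, genes in inverted.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


@dataclass
class GeneGeneEdges:
    """Undirected gene-gene interaction edges (no self-loops)."""

    edges: set

    def __post_init__(self) -> None:
        clean = set()
        for e in self.edges:
            t = tuple(e)
            if len(t) != 2 or t[0] == t[1]:
                raise ValueError(f"self-loop or malformed edge: {t!r}")
            clean.add(frozenset(t))
        self.edges = clean

    def adjacency(self, genes: Sequence[str], add_self_edges: bool = True) -> np.ndarray:
        """Binary |G| x |G| adjacency; genes without any edge keep a self-edge
        so no gene is silently discarded downstream."""
        idx = {g: i for i, g in enumerate(genes)}
        a = np.zeros((len(genes), len(genes)), dtype=np.float32)
        for e in self.edges:
            u, v = tuple(e)
            if u in idx and v in idx:
                a[idx[u], idx[v]] = 1.0
                a[idx[v], idx[u]] = 1.0
        if add_self_edges:
            np.fill_diagonal(a, 1.0)
        return a


def read_gene_edges(path: str | Path) -> GeneGeneEdges:
    """Read a 2-column TSV of gene-gene edges."""
    edges = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise SchemaError(f"malformed edge line: {line[:80]!r}")
        edges.add(frozenset(parts[:2]))
    return GeneGeneEdges(edges=edges)
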