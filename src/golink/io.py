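"""File formats, gene-synonym mapping, and the file-based pipeline runner.

Everything tabular is TSV with a header row; the only non-TSV outputs are
small JSON sidecars (index sets, undefined flags, the run manifest) and a
GraphML export of the network.  Every writer here has a matching reader
that reconstructs the in-memory object exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from golink import __version__
from golink.association import PValueMatrix, SimilarityMatrix
from golink.corpus import AbstractRecord, CooccurrenceCounts, TermDictionary
from golink.network import CommunityPartition, GeneNetwork
from golink.pipeline import PipelineResult, analyze_records

__all__ = [
    "SynonymTable",
    "RunConfig",
    "map_to_hgnc",
    "run_pipeline",
    "read_dictionary",
    "write_dictionary",
    "read_mentions",
    "write_mentions",
    "read_counts",
    "write_counts",
    "read_pvalues",
    "write_pvalues",
    "write_pvalue_matrix_tsv",
    "read_similarity",
    "write_similarity",
    "write_similarity_long",
    "read_network",
    "write_network",
    "write_network_edges",
    "read_partition",
    "write_partition",
    "read_enrichment",
    "write_enrichment",
    "read_synonyms",
]


class FormatError(ValueError):
    """A malformed input file; the message names the file and line."""


def _open_rows(path: Path, expected_header: list[str]):
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}:1: empty file, expected header {expected_header}")
        if header != expected_header:
            raise FormatError(
                f"{path}:1: bad header {header}, expected {expected_header}"
            )
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(expected_header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(expected_header)} columns, got {len(row)}"
                )
            rows.append((lineno, row))
    return rows


def _write_rows(path: Path, header: list[str], rows) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


# ---------------------------------------------------------------------------
# dictionaries and mentions
# ---------------------------------------------------------------------------

def write_dictionary(dictionary: TermDictionary, path: Path) -> None:
    """One ``(term_id, surface_name)`` row per name; empty name sets keep
    the term visible through a single row with an empty name field."""
    rows = []
    for term_id in sorted(dictionary.entries):
        names = sorted(dictionary.entries[term_id])
        if names:
            rows.extend((term_id, n) for n in names)
        else:
            rows.append((term_id, ""))
    _write_rows(path, ["term_id", "surface_name"], rows)


def read_dictionary(path: Path, kind: str) -> TermDictionary:
    entries: dict[str, set[str]] = {}
    for lineno, (term_id, name) in _open_rows(Path(path), ["term_id", "surface_name"]):
        if not term_id:
            raise FormatError(f"{path}:{lineno}: empty term_id")
        entries.setdefault(term_id, set())
        if name.strip():
            entries[term_id].add(name)
    return TermDictionary(kind, {k: frozenset(v) for k, v in entries.items()})


def write_mentions(records: list[AbstractRecord], path: Path) -> None:
    """Long mention table: ``abstract_id, term_kind, term_id``."""
    rows = []
    for rec in records:
        for g in sorted(rec.genes):
            rows.append((rec.abstract_id, "gene", g))
        for t in sorted(rec.gos):
            rows.append((rec.abstract_id, "go", t))
    _write_rows(path, ["abstract_id", "term_kind", "term_id"], rows)


def read_mentions(path: Path) -> list[AbstractRecord]:
    genes: dict[str, set[str]] = {}
    gos: dict[str, set[str]] = {}
    order: list[str] = []
    for lineno, (aid, kind, term) in _open_rows(Path(path), ["abstract_id", "term_kind", "term_id"]):
        if kind not in ("gene", "go"):
            raise FormatError(f"{path}:{lineno}: term_kind must be 'gene' or 'go', got {kind!r}")
        if not aid or not term:
            raise FormatError(f"{path}:{lineno}: empty abstract_id or term_id")
        if aid not in genes:
            genes[aid] = set()
            gos[aid] = set()
            order.append(aid)
        (genes if kind == "gene" else gos)[aid].add(term)
    return [
        AbstractRecord(abstract_id=aid, genes=frozenset(genes[aid]), gos=frozenset(gos[aid]))
        for aid in order
    ]


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def write_counts(counts: CooccurrenceCounts, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "header.json", "w") as fh:
        json.dump({"n_total": counts.n_total}, fh, indent=2)
        fh.write("\n")
    _write_rows(outdir / "gene_margins.tsv", ["gene", "n_abstracts"],
                sorted(counts.n_gene.items()))
    _write_rows(outdir / "go_margins.tsv", ["go_id", "n_abstracts"],
                sorted(counts.n_go.items()))
    _write_rows(outdir / "joint.tsv", ["gene", "go_id", "n"],
                sorted((g, t, n) for (g, t), n in counts.n_joint.items()))
    _write_rows(outdir / "gene_joint.tsv", ["gene_a", "gene_b", "n"],
                sorted((a, b, n) for (a, b), n in counts.n_gene_joint.items()))


def _int_field(path, lineno, value, what) -> int:
    try:
        n = int(value)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: {what} is not an integer: {value!r}")
    if n < 0:
        raise FormatError(f"{path}:{lineno}: {what} is negative: {n}")
    return n


def read_counts(outdir: Path) -> CooccurrenceCounts:
    outdir = Path(outdir)
    with open(outdir / "header.json") as fh:
        n_total = int(json.load(fh)["n_total"])
    n_gene = {
        g: _int_field(outdir / "gene_margins.tsv", ln, n, "gene margin")
        for ln, (g, n) in _open_rows(outdir / "gene_margins.tsv", ["gene", "n_abstracts"])
    }
    n_go = {
        t: _int_field(outdir / "go_margins.tsv", ln, n, "GO margin")
        for ln, (t, n) in _open_rows(outdir / "go_margins.tsv", ["go_id", "n_abstracts"])
    }
    n_joint = {
        (g, t): _int_field(outdir / "joint.tsv", ln, n, "joint count")
        for ln, (g, t, n) in _open_rows(outdir / "joint.tsv", ["gene", "go_id", "n"])
    }
    n_gene_joint = {
        (a, b): _int_field(outdir / "gene_joint.tsv", ln, n, "gene joint count")
        for ln, (a, b, n) in _open_rows(outdir / "gene_joint.tsv", ["gene_a", "gene_b", "n"])
    }
    counts = CooccurrenceCounts(
        n_total=n_total, n_gene=n_gene, n_go=n_go,
        n_joint=n_joint, n_gene_joint=n_gene_joint,
    )
    counts.validate()
    return counts


# ---------------------------------------------------------------------------
# p-values and similarities
# ---------------------------------------------------------------------------

def write_pvalues(pmat: PValueMatrix, base: Path) -> None:
    """``<base>.long.tsv`` (gene, go_id, p) plus ``<base>.meta.json`` holding
    the full gene/GO index sets (a term may be indexed yet have no pairs)."""
    base = Path(base)
    _write_rows(
        base.with_suffix(".long.tsv"), ["gene", "go_id", "p"],
        sorted((g, t, repr(p)) for (g, t), p in pmat.p.items()),
    )
    with open(base.with_suffix(".meta.json"), "w") as fh:
        json.dump({"genes": list(pmat.genes), "gos": list(pmat.gos)}, fh)
        fh.write("\n")


def read_pvalues(base: Path) -> PValueMatrix:
    base = Path(base)
    with open(base.with_suffix(".meta.json")) as fh:
        meta = json.load(fh)
    long_path = base.with_suffix(".long.tsv")
    p = {}
    for lineno, (g, t, val) in _open_rows(long_path, ["gene", "go_id", "p"]):
        try:
            p[(g, t)] = float(val)
        except ValueError:
            raise FormatError(f"{long_path}:{lineno}: p is not a number: {val!r}")
    return PValueMatrix(genes=tuple(meta["genes"]), gos=tuple(meta["gos"]), p=p)


def write_pvalue_matrix_tsv(pmat: PValueMatrix, path: Path) -> None:
    """Dense gene x GO matrix with missing pairs as empty cells (export only)."""
    frame = pd.DataFrame(
        [[pmat.p.get((g, t), None) for t in pmat.gos] for g in pmat.genes],
        index=pd.Index(pmat.genes, name="gene"),
        columns=pmat.gos,
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", na_rep="")


def write_similarity(sim: SimilarityMatrix, base: Path) -> None:
    """``<base>.matrix.tsv`` (square, with gene index) plus ``<base>.meta.json``
    recording which genes are flagged undefined."""
    base = Path(base)
    frame = pd.DataFrame(sim.values, index=pd.Index(sim.genes, name="gene"),
                         columns=sim.genes)
    base.parent.mkdir(parents=True, exist_ok=True)
    # repr of the plain float round-trips exactly through read_csv
    frame.to_csv(base.with_suffix(".matrix.tsv"), sep="\t",
                 float_format=lambda v: repr(float(v)))
    with open(base.with_suffix(".meta.json"), "w") as fh:
        json.dump({"undefined": sorted(sim.undefined)}, fh)
        fh.write("\n")


def read_similarity(base: Path) -> SimilarityMatrix:
    base = Path(base)
    frame = pd.read_csv(base.with_suffix(".matrix.tsv"), sep="\t", index_col=0,
                        float_precision="round_trip")
    with open(base.with_suffix(".meta.json")) as fh:
        meta = json.load(fh)
    return SimilarityMatrix(
        genes=tuple(frame.index),
        values=frame.to_numpy(dtype=float),
        undefined=frozenset(meta["undefined"]),
    )


def write_similarity_long(sim: SimilarityMatrix, path: Path) -> None:
    """Long export (gene_a, gene_b, gamma) of the upper triangle."""
    rows = []
    n = len(sim.genes)
    for i in range(n):
        for j in range(i + 1, n):
            rows.append((sim.genes[i], sim.genes[j], repr(float(sim.values[i, j]))))
    _write_rows(path, ["gene_a", "gene_b", "gamma"], rows)


# ---------------------------------------------------------------------------
# networks, partitions, enrichment
# ---------------------------------------------------------------------------

def write_network_edges(net: GeneNetwork, path: Path) -> None:
    rows = sorted(
        (min(a, b), max(a, b), repr(float(d["weight"])))
        for a, b, d in net.graph.edges(data=True)
    )
    _write_rows(path, ["gene_a", "gene_b", "gamma"], rows)


def write_network(net: GeneNetwork, path: Path,
                  partition: CommunityPartition | None = None) -> None:
    """GraphML export with edge weights, the cutoff, and (optionally) the
    community label of every node."""
    G = nx.Graph(cutoff=float(net.cutoff))
    for node in sorted(net.graph.nodes):
        attrs = {}
        if partition is not None and node in partition.labels:
            attrs["community"] = int(partition.labels[node])
        G.add_node(node, **attrs)
    for a, b, d in sorted(net.graph.edges(data=True)):
        G.add_edge(a, b, weight=float(d["weight"]))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(G, path)


def read_network(path: Path) -> GeneNetwork:
    G = nx.read_graphml(path)
    cutoff = float(G.graph.get("cutoff", 0.0))
    H = nx.Graph(cutoff=cutoff)
    H.add_nodes_from(G.nodes)
    for a, b, d in G.edges(data=True):
        H.add_edge(a, b, weight=float(d["weight"]))
    return GeneNetwork(graph=H, cutoff=cutoff)


def write_partition(part: CommunityPartition, path: Path) -> None:
    _write_rows(path, ["gene", "community"], sorted(part.labels.items()))


def read_partition(path: Path, seed: int | None = None) -> CommunityPartition:
    labels = {
        g: _int_field(path, ln, c, "community label")
        for ln, (g, c) in _open_rows(Path(path), ["gene", "community"])
    }
    return CommunityPartition(labels=labels, seed=seed)


def write_enrichment(enrichment: pd.DataFrame, path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    enrichment.to_csv(path, sep="\t", index=False)


def read_enrichment(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# synonym mapping
# ---------------------------------------------------------------------------

@dataclass
class SynonymTable:
    """Normalized gene synonym -> HGNC symbol lookup.

    Normalization is case-folding plus whitespace trimming; each normalized
    synonym must map to exactly one symbol (collisions are rejected when the
    table is loaded, with a report of every conflict).
    """

    mapping: dict[str, str]
    provenance: str = ""

    @staticmethod
    def normalize(symbol: str) -> str:
        return " ".join(symbol.split()).casefold()


def read_synonyms(path: Path, provenance: str = "") -> SynonymTable:
    path = Path(path)
    mapping: dict[str, str] = {}
    first_line: dict[str, int] = {}
    collisions = []
    for lineno, (syn, hgnc) in _open_rows(path, ["synonym", "hgnc"]):
        if not syn.strip() or not hgnc.strip():
            raise FormatError(f"{path}:{lineno}: empty synonym or hgnc field")
        key = SynonymTable.normalize(syn)
        if key in mapping and mapping[key] != hgnc:
            collisions.append(
                f"{path}:{lineno}: synonym {syn!r} maps to {hgnc!r} but line "
                f"{first_line[key]} already maps it to {mapping[key]!r}"
            )
            continue
        if key not in mapping:
            mapping[key] = hgnc
            first_line[key] = lineno
    if collisions:
        raise FormatError(
            "ambiguous synonym table:\n" + "\n".join(collisions)
        )
    return SynonymTable(mapping=mapping, provenance=provenance or str(path))


def map_to_hgnc(
    symbols: list[str], table: SynonymTable
) -> tuple[list[tuple[str, str]], list[str]]:
    """Map input symbols to HGNC ids; exact match after normalization only.

    Returns ``(mapped, unmapped)`` preserving the input order.  Unmapped
    symbols are reported, never guessed.
    """
    mapped = []
    unmapped = []
    for sym in symbols:
        hit = table.mapping.get(SynonymTable.normalize(sym))
        if hit is None:
            unmapped.append(sym)
        else:
            mapped.append((sym, hit))
    return mapped, unmapped


# ---------------------------------------------------------------------------
# run configuration and the file-based pipeline
# ---------------------------------------------------------------------------

_PRESET_QUANTILES = {"median": 0.50, "moderate": 0.95, "high": 0.99}


@dataclass
class RunConfig:
    """Validated parameters of a full pipeline run.

    ``cutoff`` may be an absolute similarity in [0, 1], a preset name
    (``median`` / ``moderate`` / ``high`` -> the 50th / 95th / 99th
    percentile of the corpus's own similarity distribution), or ``None`` to
    use ``cutoff_quantile`` directly.
    """

    mentions: Path
    outdir: Path
    cutoff: float | str | None = None
    cutoff_quantile: float | None = 0.99
    floor: float = 1e-6
    log_base: float | None = None
    percentile_method: str = "linear"
    seed: int = 0
    max_iter: int = 100

    def __post_init__(self) -> None:
        self.mentions = Path(self.mentions)
        self.outdir = Path(self.outdir)
        if isinstance(self.cutoff, str):
            if self.cutoff not in _PRESET_QUANTILES:
                raise ValueError(
                    f"unknown cutoff preset {self.cutoff!r}; "
                    f"expected one of {sorted(_PRESET_QUANTILES)}"
                )
            self.cutoff_quantile = _PRESET_QUANTILES[self.cutoff]
            self.cutoff = None
        if self.cutoff is not None and not 0.0 <= float(self.cutoff) <= 1.0:
            raise ValueError(f"cutoff must lie in [0, 1], got {self.cutoff}")
        if self.cutoff is None and self.cutoff_quantile is None:
            raise ValueError("one of cutoff / cutoff_quantile must be set")
        if self.cutoff_quantile is not None and not 0.0 <= self.cutoff_quantile <= 1.0:
            raise ValueError(f"cutoff_quantile must lie in [0, 1], got {self.cutoff_quantile}")
        if not 0.0 < self.floor < 1.0:
            raise ValueError(f"floor must lie in (0, 1), got {self.floor}")
        if self.log_base is not None and self.log_base <= 1.0:
            raise ValueError(f"log_base must be > 1, got {self.log_base}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"{path}:1: run config must be a mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise FormatError(f"{path}: {exc}") from None

    def to_yaml(self, path: Path) -> None:
        data = asdict(self)
        data["mentions"] = str(self.mentions)
        data["outdir"] = str(self.outdir)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Read mentions, run the full association pipeline, write every artifact.

    Outputs under ``cfg.outdir``: the counts directory, p-values (long +
    dense), similarities (square + long), the network (edge TSV + GraphML
    with communities), the partition, the enrichment table, and a JSON
    manifest recording the package version, the seed and all parameters.
    Deterministic: re-running the same config yields byte-identical files.
    """
    records = read_mentions(cfg.mentions)
    result = analyze_records(
        records,
        cutoff=cfg.cutoff if not isinstance(cfg.cutoff, str) else None,
        cutoff_quantile=cfg.cutoff_quantile,
        floor=cfg.floor,
        log_base=cfg.log_base,
        percentile_method=cfg.percentile_method,
        seed=cfg.seed,
        max_iter=cfg.max_iter,
    )
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(result.counts, out / "counts")
    write_pvalues(result.pvalues, out / "pvalues")
    write_pvalue_matrix_tsv(result.pvalues, out / "pvalues.matrix.tsv")
    write_similarity(result.similarity, out / "similarity")
    write_similarity_long(result.similarity, out / "similarity.long.tsv")
    write_network_edges(result.network, out / "network.edges.tsv")
    write_network(result.network, out / "network.graphml", result.partition)
    write_partition(result.partition, out / "communities.tsv")
    write_enrichment(result.enrichment, out / "enrichment.tsv")
    manifest = {
        "package": "golink",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "cutoff": result.cutoff,
            "cutoff_quantile": result.cutoff_quantile,
            "floor": cfg.floor,
            "log_base": cfg.log_base,
            "percentile_method": cfg.percentile_method,
            "max_iter": cfg.max_iter,
        },
        "inputs": {"mentions": str(cfg.mentions)},
        "n_abstracts_with_mentions": result.counts.n_total,
        "n_genes": len(result.pvalues.genes),
        "n_go_terms": len(result.pvalues.gos),
        "n_edges": result.network.n_edges,
        "n_communities": result.partition.n_communities,
        "converged": result.partition.converged,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
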