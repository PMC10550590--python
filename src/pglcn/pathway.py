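"""Biological prior construction and synthetic cohorts.

Builds the fixed pathway graph (nodes = Reactome pathways, edges =
parent/child hierarchy relations, self-loops on the diagonal), reduces
gene-level multi-omics matrices (mRNA expression G, copy number C,
methylation beta values M) to per-patient pathway feature matrices K_p via
per-pathway PCA, assigns tumor-mutation-burden labels (high iff strictly
more than 10 mutations per megabase), and simulates cohorts with planted
pathway-level group differences for testing and calibration.

Feature layout: with q principal components per omic, each patient's K_p is
a (pathways x 3q) matrix whose column blocks are, in order, expression PCs
[0..q), copy-number PCs [q..2q), methylation PCs [2q..3q).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

#: default exome footprint (megabases) used as the TMB denominator
DEFAULT_COVERED_MB = 38.0
#: mutations-per-megabase threshold; "high TMB" is strictly above this
TMB_THRESHOLD = 10.0

OMICS = ("expression", "cnv", "methylation")


@dataclass
class PathwayGraph:
    """Fixed prior: pathway adjacency plus gene-set membership."""

    pathway_ids: list
    adjacency: np.ndarray            # (p, p) binary, symmetric, unit diagonal
    gene_sets: dict                  # pathway id -> set of gene symbols

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.shape != (len(self.pathway_ids),) * 2:
            raise ValueError("adjacency shape does not match pathway_ids")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.array_equal(np.diag(a), np.ones(len(a))):
            raise ValueError("adjacency diagonal must be all ones")


@dataclass
class OmicsCohort:
    """Gene-level multi-omics matrices over one patient cohort.

    All three matrices share patient (row) and gene (column) ordering.
    Methylation is on the beta-value scale, in [0, 1].
    """

    patient_ids: list
    gene_ids: list
    expression: np.ndarray           # (n, r)
    copy_number: np.ndarray          # (n, r)
    methylation: np.ndarray          # (n, r), beta values
    mutation_rate: np.ndarray        # (n,) mutations per megabase
    tmb_label: np.ndarray            # (n,) int, 1 iff mutation_rate > 10

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


@dataclass
class PathwayFeatureTensor:
    """Per-patient pathway-level PCA features (n patients x p pathways x 3q)."""

    values: np.ndarray
    pathway_ids: list
    q: int

    @property
    def n_columns(self) -> int:
        return self.values.shape[2]

    def omic_block(self, omic: str) -> np.ndarray:
        """Columns of one omic across all pathways: (n, p, q) view."""
        k = OMICS.index(omic)
        return self.values[:, :, k * self.q : (k + 1) * self.q]


# ------------------------------------------------------------------ parsing

def parse_reactome_hierarchy(relation_records, keep_ids=None):
    """Adjacency from parent-child pathway relations.

    ``relation_records``: iterable of (parent_id, child_id) pairs, or a path
    to a two-column tab-separated file (ReactomePathwaysRelation.txt dialect).
    ``keep_ids``: optional ordered pathway universe; pairs mentioning ids
    outside it are dropped (count logged). Without it the universe is all
    ids seen, sorted.

    Returns (pathway_ids, adjacency): symmetric 0/1 matrix, unit diagonal.
    """
    if isinstance(relation_records, (str, Path)):
        pairs = []
        with open(relation_records) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"malformed relation line: {line!r}")
                pairs.append((parts[0], parts[1]))
    else:
        pairs = [(str(a), str(b)) for a, b in relation_records]
    if not pairs:
        raise ValueError("empty relation record set")

    if keep_ids is None:
        ids = sorted({x for pair in pairs for x in pair})
    else:
        ids = list(keep_ids)
    index = {pid: i for i, pid in enumerate(ids)}
    a = np.eye(len(ids), dtype=int)
    dropped = 0
    for parent, child in pairs:
        if parent in index and child in index:
            i, j = index[parent], index[child]
            a[i, j] = a[j, i] = 1
        else:
            dropped += 1
    if dropped:
        logger.info("parse_reactome_hierarchy: dropped %d pairs outside the pathway universe", dropped)
    return ids, a


def parse_genesets(gmt_records):
    """Pathway gene sets from GMT records.

    ``gmt_records``: path to a GMT file or iterable of lines/record tuples.
    Each record is (pathway id, description, gene, gene, ...). Returns a
    dict pathway id -> set of gene symbols. Genes absent from a cohort are
    filtered later, at featurization time.
    """
    if isinstance(gmt_records, (str, Path)):
        with open(gmt_records) as fh:
            lines = fh.readlines()
    else:
        lines = list(gmt_records)
    gene_sets = {}
    for lineno, rec in enumerate(lines, start=1):
        if isinstance(rec, str):
            rec = rec.rstrip("\n")
            if not rec:
                continue
            parts = rec.split("\t")
        else:
            parts = list(rec)
        if len(parts) < 2:
            raise ValueError(f"malformed GMT record at line {lineno}: {parts!r}")
        pid, genes = parts[0], [g for g in parts[2:] if g]
        if not genes:
            logger.warning("parse_genesets: pathway %s has an empty gene list", pid)
        gene_sets[pid] = set(genes)
    return gene_sets


def build_pathway_graph(relation_records, gmt_records, cohort_genes=None) -> PathwayGraph:
    """Assemble the prior over pathways present in both inputs.

    Pathways whose gene set has no overlap with ``cohort_genes`` (when
    given) are excluded and the adjacency re-indexed.
    """
    gene_sets = parse_genesets(gmt_records)
    ids_all, _ = parse_reactome_hierarchy(relation_records)
    keep = [pid for pid in ids_all if pid in gene_sets]
    if cohort_genes is not None:
        cohort_genes = set(cohort_genes)
        kept = []
        for pid in keep:
            if gene_sets[pid] & cohort_genes:
                kept.append(pid)
            else:
                logger.warning("build_pathway_graph: pathway %s has no cohort genes; excluded", pid)
        keep = kept
    if not keep:
        raise ValueError("no pathways survive the hierarchy/gene-set/cohort intersection")
    ids, a = parse_reactome_hierarchy(relation_records, keep_ids=keep)
    return PathwayGraph(pathway_ids=ids, adjacency=a, gene_sets={pid: set(gene_sets[pid]) for pid in ids})


def write_hierarchy(graph: PathwayGraph, path) -> None:
    """Write the off-diagonal adjacency back out as parent-child relations."""
    with open(path, "w") as fh:
        p = graph.n_pathways
        for i in range(p):
            for j in range(i + 1, p):
                if graph.adjacency[i, j]:
                    fh.write(f"{graph.pathway_ids[i]}\t{graph.pathway_ids[j]}\n")


# --------------------------------------------------------------- TMB labels

def compute_tmb_labels(mutation_counts, covered_megabases=DEFAULT_COVERED_MB):
    """Mutations-per-megabase rates and high/low TMB labels.

    ``label = 1`` iff ``rate > 10`` strictly: 380 mutations over 38 Mb is a
    rate of exactly 10 and labels low.
    """
    counts = np.asarray(mutation_counts, dtype=float)
    mb = np.asarray(covered_megabases, dtype=float)
    if np.any(counts < 0):
        raise ValueError("mutation counts must be nonnegative")
    if np.any(mb <= 0):
        raise ValueError("covered megabases must be positive")
    rate = counts / mb
    label = (rate > TMB_THRESHOLD).astype(int)
    return rate, label


# ------------------------------------------------------------ featurization

def _fix_sign(components: np.ndarray) -> np.ndarray:
    """Deterministic PC sign: largest-magnitude loading of each axis positive."""
    comps = components.copy()
    for k in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] *= -1
    return comps


def pathway_pca_features(
    cohort: OmicsCohort,
    graph: PathwayGraph,
    q: int = 2,
    fit_patients=None,
) -> PathwayFeatureTensor:
    """Per-pathway, per-omic PCA feature tensor K_p.

    For every pathway and omic, the pathway's gene columns are centered with
    the ``fit_patients`` means and projected on the top-q principal axes
    estimated from ``fit_patients`` only (all patients by default); held-out
    rows never influence centering or the axes. Pathways with fewer usable
    genes (or fitting rows) than q get their missing PC columns padded with
    zeros.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    n = cohort.n_patients
    fit_idx = np.arange(n) if fit_patients is None else np.asarray(fit_patients, dtype=int)
    if fit_idx.size < 2:
        raise ValueError("need at least 2 fitting patients")
    gene_index = {g: i for i, g in enumerate(cohort.gene_ids)}
    mats = {
        "expression": np.asarray(cohort.expression, dtype=float),
        "cnv": np.asarray(cohort.copy_number, dtype=float),
        "methylation": np.asarray(cohort.methylation, dtype=float),
    }
    p = graph.n_pathways
    out = np.zeros((n, p, 3 * q))
    for pi, pid in enumerate(graph.pathway_ids):
        cols = sorted(gene_index[g] for g in graph.gene_sets[pid] if g in gene_index)
        if not cols:
            logger.warning("pathway %s has no genes in the cohort; features stay zero", pid)
            continue
        for k, omic in enumerate(OMICS):
            sub = mats[omic][:, cols]
            n_comp = min(q, len(cols), fit_idx.size - 1)
            if n_comp < q:
                logger.info("pathway %s/%s: only %d PCs available, padding to %d", pid, omic, n_comp, q)
            if n_comp < 1:
                continue
            fit_block = sub[fit_idx]
            if np.allclose(fit_block.std(axis=0), 0.0):
                continue  # constant genes: centered projection is identically zero
            pca = PCA(n_components=n_comp, svd_solver="full")
            pca.fit(fit_block)
            comps = _fix_sign(pca.components_)
            scores = (sub - pca.mean_) @ comps.T
            out[:, pi, k * q : k * q + n_comp] = scores
    return PathwayFeatureTensor(values=out, pathway_ids=list(graph.pathway_ids), q=q)


# ----------------------------------------------------------------- simulator

def simulate_pathway_graph(
    n_pathways: int = 30,
    genes_per_pathway: int = 15,
    n_effect: int = 10,
    seed: int = 0,
):
    """A synthetic stand-in for the Reactome prior.

    Random tree hierarchy over ``n_pathways`` pathways with disjoint gene
    sets; the first ``n_effect`` pathways are wired into a connected chain so
    that a planted signal spans a connected subgraph. Returns
    (PathwayGraph, effect_pathway_ids).
    """
    rng = np.random.default_rng(seed)
    ids = [f"PW{i:03d}" for i in range(n_pathways)]
    pairs = [(ids[i], ids[i + 1]) for i in range(n_effect - 1)]  # effect chain
    for i in range(n_effect, n_pathways):
        parent = int(rng.integers(0, i))
        pairs.append((ids[parent], ids[i]))
    gene_sets = {
        ids[i]: {f"G{i * genes_per_pathway + j:05d}" for j in range(genes_per_pathway)}
        for i in range(n_pathways)
    }
    _, a = parse_reactome_hierarchy(pairs, keep_ids=ids)
    return PathwayGraph(pathway_ids=ids, adjacency=a, gene_sets=gene_sets), ids[:n_effect]


def simulate_multiomics_cohort(
    n_patients: int,
    graph: PathwayGraph,
    effect_pathways,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    high_fraction: float = 0.3,
    seed: int = 0,
) -> OmicsCohort:
    """Simulate a cohort with a planted pathway-level TMB signal.

    High-TMB patients (drawn with prevalence ``high_fraction``) receive a
    mean shift of ``effect_size`` on expression of all genes in the effect
    pathways, and half-size shifts on copy number and (pre-squash)
    methylation; every other value is independent N(0, noise_sd) noise.
    Methylation is squashed through a logistic to the beta-value range.
    Mutation rates are drawn consistently with the labels (high group
    strictly above 10/Mb).
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if not 0 < high_fraction < 1:
        raise ValueError("high_fraction must be in (0, 1)")
    effect_pathways = list(effect_pathways)
    unknown = [p for p in effect_pathways if p not in graph.gene_sets]
    if unknown:
        raise ValueError(f"effect pathways not in graph: {unknown}")

    rng = np.random.default_rng(seed)
    genes = sorted(set().union(*(graph.gene_sets[p] for p in graph.pathway_ids)))
    gene_index = {g: i for i, g in enumerate(genes)}
    r = len(genes)
    labels = (rng.random(n_patients) < high_fraction).astype(int)

    effect_cols = sorted({gene_index[g] for p in effect_pathways for g in graph.gene_sets[p] if g in gene_index})
    shift = np.zeros((n_patients, r))
    shift[np.ix_(labels == 1, effect_cols)] = 1.0

    expr = rng.normal(0.0, noise_sd, (n_patients, r)) + effect_size * shift
    cnv = rng.normal(0.0, noise_sd, (n_patients, r)) + 0.5 * effect_size * shift
    meth_raw = rng.normal(0.0, noise_sd, (n_patients, r)) + 0.5 * effect_size * shift
    meth = 1.0 / (1.0 + np.exp(-meth_raw))

    rate = np.where(
        labels == 1,
        TMB_THRESHOLD + 0.5 + rng.gamma(2.0, 4.0, n_patients),
        rng.uniform(0.0, TMB_THRESHOLD, n_patients),
    )
    _, check = compute_tmb_labels(rate * DEFAULT_COVERED_MB, DEFAULT_COVERED_MB)
    assert np.array_equal(check, labels)
    return OmicsCohort(
        patient_ids=[f"PT{i:04d}" for i in range(n_patients)],
        gene_ids=genes,
        expression=expr,
        copy_number=cnv,
        methylation=meth,
        mutation_rate=rate,
        tmb_label=labels,
    )
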