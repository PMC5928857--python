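"""Single-cell immune subtyping from mass-cytometry event tables.

The workflow mirrors SPADE/SCAFFOLD-style analysis: arcsinh transform,
per-sample density-dependent downsampling, a fixed-k centroid clustering of
pooled cells into nodes, landmark/phenotype annotation of nodes, a
cosine-similarity scaffold graph, unsupervised two-way subtyping of samples
from node-composition profiles, and differential statistics (per-phenotype
paired t tests across corresponding nodes; the Z-ratio activation statistic
with the |Z| >= 1.96 significance rule).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .phenotypes import (
    ALL_MARKERS,
    EXHAUSTED_CD8,
    LINEAGE_MARKERS,
    PhenotypeDefinition,
    validate_phenotypes,
)

logger = logging.getLogger(__name__)

SAMPLE_COL = "sample_id"

#: Two-sided standard-normal critical value at P < 0.05, used as the
#: default Z-ratio significance cutoff.
Z_RATIO_CUTOFF = 1.96


@dataclass
class CellEventTable:
    """Cells-by-markers intensity table for one or more samples.

    ``data`` holds one row per cell with a ``sample_id`` column plus one
    column per marker.  ``transformed`` records whether intensities are on
    the arcsinh scale.
    """

    data: pd.DataFrame
    markers: tuple[str, ...]
    transformed: bool = False

    def __post_init__(self) -> None:
        self.markers = tuple(self.markers)
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        missing = [m for m in (SAMPLE_COL, *self.markers) if m not in self.data.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        if self.data[list(self.markers)].isna().any().any():
            raise ValueError("event table contains missing marker values")
        counts = self.data[SAMPLE_COL].value_counts()
        if len(counts) == 0 or (counts < 1).any():
            raise ValueError("every sample needs at least one cell")

    @property
    def samples(self) -> list[str]:
        return sorted(self.data[SAMPLE_COL].unique().tolist())

    def matrix(self, markers: Sequence[str] | None = None) -> np.ndarray:
        return self.data[list(markers or self.markers)].to_numpy(dtype=float)


@dataclass
class ScaffoldNodeSet:
    """Clustered cell populations (nodes) with annotation.

    ``medians``: nodes x markers median intensity; ``fractions``: samples x
    nodes cell fractions (each row sums to 1); ``phenotypes``: node ->
    phenotype label (after :func:`assign_phenotypes`); ``landmarks``: node ->
    bool, True for phenotype-representative (landmark) nodes.
    """

    medians: pd.DataFrame
    fractions: pd.DataFrame
    phenotypes: pd.Series | None = None
    landmarks: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.medians.index.equals(pd.Index(self.fractions.columns)):
            raise ValueError("medians index and fractions columns must match")
        sums = self.fractions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-sample node fractions must sum to 1")
        if self.phenotypes is not None:
            if not self.phenotypes.index.equals(self.medians.index):
                raise ValueError("phenotype labels must cover every node")
            if self.phenotypes.isna().any():
                raise ValueError("every node needs exactly one phenotype label")

    @property
    def node_ids(self) -> pd.Index:
        return self.medians.index

    def phenotype_fractions(self) -> pd.DataFrame:
        """Per-sample cell fraction aggregated to phenotype level."""
        if self.phenotypes is None:
            raise ValueError("nodes are not phenotype-annotated yet")
        return self.fractions.T.groupby(self.phenotypes).sum().T


@dataclass
class ScaffoldGraph:
    """Complete cosine-similarity graph over annotated nodes."""

    nodes: ScaffoldNodeSet
    similarity: pd.DataFrame  # full symmetric node x node cosine matrix

    def __post_init__(self) -> None:
        sim = self.similarity.to_numpy()
        if not np.allclose(sim, sim.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if sim.min() < -1 - 1e-9 or sim.max() > 1 + 1e-9:
            raise ValueError("cosine similarities must lie in [-1, 1]")

    def to_networkx(self, retention_quantile: float = 0.0):
        """Export as a networkx graph, pruning edges below the given
        weight quantile (0 keeps the complete graph); no self-edges."""
        import networkx as nx

        ids = list(self.similarity.index)
        weights = [
            self.similarity.iat[i, j]
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
        ]
        threshold = float(np.quantile(weights, retention_quantile)) if weights else 0.0
        g = nx.Graph()
        for node in ids:
            attrs = {"landmark": bool(self.nodes.landmarks.get(node, False))
                     if self.nodes.landmarks is not None else False}
            if self.nodes.phenotypes is not None:
                attrs["phenotype"] = self.nodes.phenotypes[node]
            g.add_node(node, **attrs)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                w = float(self.similarity.iat[i, j])
                if w >= threshold:
                    g.add_edge(ids[i], ids[j], weight=w)
        return g


def arcsinh_transform(raw: CellEventTable, cofactor: float = 5.0) -> CellEventTable:
    """Apply the standard cytometry scaling x -> asinh(x / cofactor)."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if raw.transformed:
        raise ValueError("event table is already arcsinh-transformed")
    data = raw.data.copy()
    data[list(raw.markers)] = np.arcsinh(data[list(raw.markers)] / cofactor)
    return CellEventTable(data=data, markers=raw.markers, transformed=True)


def _local_density(points: np.ndarray, k: int) -> np.ndarray:
    """k-NN density estimate: k over the distance to the k-th neighbour."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dist, _ = nn.kneighbors(points)
    radius = dist[:, -1]
    return k / (radius + 1e-12)


def density_downsample(
    events: CellEventTable,
    target_fraction: float = 0.5,
    k_neighbors: int = 15,
    seed: int = 0,
    markers: Sequence[str] | None = None,
) -> CellEventTable:
    """Density-dependent downsampling, applied to each sample separately.

    Each cell's local density is estimated with a k-NN estimator; cells are
    kept with probability ``min(1, target / density)`` where ``target`` is
    the ``target_fraction`` quantile of that sample's densities.  Dense
    regions are thinned toward the target local density while sparse cells
    are always retained.  The per-sample random stream is derived from
    ``(seed, sample_id)`` so one sample's kept set never depends on the
    other samples present.
    """
    if not events.transformed:
        raise ValueError("downsampling expects arcsinh-transformed events")
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in (0, 1]")
    use = list(markers or [m for m in LINEAGE_MARKERS if m in events.markers]
               or events.markers)
    kept_parts = []
    for sample, sub in events.data.groupby(SAMPLE_COL, sort=True):
        pts = sub[use].to_numpy(dtype=float)
        if len(sub) <= k_neighbors:
            warnings.warn(
                f"sample {sample!r} has fewer cells than k_neighbors; keeping all",
                stacklevel=2,
            )
            kept_parts.append(sub)
            continue
        density = _local_density(pts, k_neighbors)
        target = np.quantile(density, target_fraction)
        keep_prob = np.minimum(1.0, target / density)
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [seed, int.from_bytes(str(sample).encode(), "little") % (2**63)]
            )
        )
        keep = rng.random(len(sub)) < keep_prob
        if not keep.any():  # degenerate guard: never drop a whole sample
            keep[int(np.argmax(keep_prob))] = True
        kept_parts.append(sub.loc[keep])
    out = pd.concat(kept_parts, axis=0)
    return CellEventTable(data=out, markers=events.markers, transformed=True)


def cluster_events(
    events: CellEventTable,
    all_events: CellEventTable | None = None,
    k: int = 500,
    seed: int = 0,
    markers: Sequence[str] | None = None,
) -> ScaffoldNodeSet:
    """Partition pooled cells into up to ``k`` nodes.

    Centroids are fitted on the (downsampled) ``events`` over the clustering
    marker subset (lineage markers by default); every cell of ``all_events``
    (default: ``events``) is then mapped to its nearest centroid, and node
    medians (all markers) and per-sample fractions are computed on the full
    assignment.  Empty nodes are dropped; the realized node count may be
    below ``k``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    use = list(markers or [m for m in LINEAGE_MARKERS if m in events.markers]
               or events.markers)
    fit_x = events.data[use].to_numpy(dtype=float)
    if k > len(fit_x):
        raise ValueError(f"k={k} exceeds the {len(fit_x)} pooled cells")
    km = KMeans(n_clusters=k, random_state=seed, n_init=4)
    km.fit(fit_x)
    full = all_events if all_events is not None else events
    assign = km.predict(full.data[use].to_numpy(dtype=float))
    labels = pd.Series(assign, index=full.data.index)
    occupied = np.sort(labels.unique())
    node_ids = pd.Index([f"node_{i:04d}" for i in range(len(occupied))], name="node")
    remap = {old: node_ids[j] for j, old in enumerate(occupied)}
    node_of = labels.map(remap)

    medians = (
        full.data[list(full.markers)]
        .groupby(node_of)
        .median()
        .reindex(node_ids)
    )
    counts = (
        pd.crosstab(full.data[SAMPLE_COL], node_of)
        .reindex(columns=node_ids, fill_value=0)
        .sort_index()
    )
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return ScaffoldNodeSet(medians=medians, fractions=fractions)


def assign_phenotypes(
    nodes: ScaffoldNodeSet,
    defs: Sequence[PhenotypeDefinition] | None = None,
    gate_threshold: float = 1.0,
    off_gate_penalty: float = 0.25,
) -> ScaffoldNodeSet:
    """Label every node with one of the gated phenotypes.

    For each phenotype the representative (landmark) node is the best gate
    match among nodes satisfying the gate (positive markers above
    ``gate_threshold`` on the arcsinh scale, negative below); the score
    rewards gated markers and mildly penalizes off-gate lineage expression
    so that nested gates (e.g. CD4 T cells vs CD25+FOXP3+ Tregs) resolve to
    distinct representatives.  Remaining nodes inherit the phenotype of the
    representative sharing their average-linkage cluster; clusters without a
    unique representative fall back to the nearest representative in marker
    space.
    """
    if defs is None:
        from .phenotypes import DEFAULT_PHENOTYPES

        defs = DEFAULT_PHENOTYPES
    lineage = [m for m in LINEAGE_MARKERS if m in nodes.medians.columns]
    validate_phenotypes(defs, nodes.medians.columns)
    med = nodes.medians

    reps: dict[str, str] = {}
    for d in defs:
        pos, neg = list(d.positive), list(d.negative)
        ok = pd.Series(True, index=med.index)
        for m in pos:
            ok &= med[m] > gate_threshold
        for m in neg:
            ok &= med[m] < gate_threshold
        if not ok.any():
            raise ValueError(f"gate for phenotype {d.name!r} is unsatisfiable on all nodes")
        off_gate = [m for m in lineage if m not in pos and m not in neg]
        score = (
            med[pos].sum(axis=1)
            - med[neg].sum(axis=1)
            - off_gate_penalty * med[off_gate].sum(axis=1)
        )
        reps[d.name] = score[ok].idxmax()

    labels = pd.Series(index=med.index, dtype=object)
    x = med[lineage].to_numpy(dtype=float)
    if len(med) > 1:
        dist = squareform(
            np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)),
            checks=False,
        )
        link = average(dist)
        clusters = pd.Series(
            fcluster(link, t=min(len(defs), len(med)), criterion="maxclust"),
            index=med.index,
        )
    else:
        clusters = pd.Series(1, index=med.index)

    rep_nodes = pd.Series({node: name for name, node in reps.items()})
    for cid, members in clusters.groupby(clusters).groups.items():
        members = pd.Index(members)
        member_reps = [n for n in members if n in rep_nodes.index]
        if len(member_reps) == 1:
            labels.loc[members] = rep_nodes[member_reps[0]]
        else:
            # ambiguous cluster: nearest representative per node
            rep_x = med.loc[rep_nodes.index, lineage].to_numpy(dtype=float)
            for n in members:
                v = med.loc[n, lineage].to_numpy(dtype=float)
                nearest = int(np.argmin(((rep_x - v) ** 2).sum(axis=1)))
                labels.loc[n] = rep_nodes.iloc[nearest]

    landmarks = pd.Series(False, index=med.index)
    landmarks.loc[list(reps.values())] = True
    return replace(nodes, phenotypes=labels, landmarks=landmarks)


def cosine_similarity_matrix(vectors: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine similarity between row vectors; zero vectors get
    similarity 0 (with a warning) and the diagonal is exactly 1."""
    x = vectors.to_numpy(dtype=float)
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn("zero median vector; cosine similarity defined as 0", stacklevel=2)
    safe = np.where(zero, 1.0, norms)
    unit = x / safe[:, None]
    sim = unit @ unit.T
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.fill_diagonal(sim, np.where(zero, 0.0, 1.0))
    sim = np.clip(sim, -1.0, 1.0)
    sim = (sim + sim.T) / 2.0
    return pd.DataFrame(sim, index=vectors.index, columns=vectors.index)


def build_scaffold_graph(nodes: ScaffoldNodeSet) -> ScaffoldGraph:
    """Build the complete cosine-similarity graph over node median vectors.

    Landmark (representative) node identities are carried on the node set;
    their flags are preserved in graph exports so layouts can pin them.
    """
    sim = cosine_similarity_matrix(nodes.medians)
    return ScaffoldGraph(nodes=nodes, similarity=sim)


def subtype_samples(
    fractions: pd.DataFrame,
    orientation_score: pd.Series | None = None,
) -> pd.Series:
    """Two-way unsupervised subtyping of samples from node compositions.

    Average-linkage hierarchical clustering on 1 - Pearson correlation
    between per-sample node-fraction profiles, cut at two clusters.  The
    cluster with the higher mean ``orientation_score`` (canonically the
    partially exhausted CD8 T-cell fraction per sample) is labeled "I"
    (good microenvironment); without a score, the cluster containing the
    lexicographically smallest sample id is labeled "I" — deterministic and
    content-based, but semantically arbitrary.
    """
    if len(fractions) < 4:
        raise ValueError("subtyping needs at least 4 samples")
    x = fractions.to_numpy(dtype=float)
    if np.any(x.std(axis=1) == 0):
        raise ValueError("degenerate correlation: a sample has an all-equal profile")
    corr = np.corrcoef(x)
    if np.isnan(corr).any():
        raise ValueError("degenerate correlation")
    dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    link = average(dist)
    two = pd.Series(fcluster(link, t=2, criterion="maxclust"), index=fractions.index)

    clusters = sorted(two.unique())
    if len(clusters) < 2:
        raise ValueError("clustering did not separate two groups")
    if orientation_score is not None:
        means = {c: orientation_score.reindex(two.index[two == c]).mean() for c in clusters}
        first = max(clusters, key=lambda c: (means[c], -c))
    else:
        anchor = min(fractions.index)
        first = two[anchor]
    return two.map(lambda c: "I" if c == first else "II").rename("subtype")


def compare_nodes(
    fractions_a: pd.Series,
    fractions_b: pd.Series,
    phenotypes: pd.Series | Mapping[str, str],
) -> pd.DataFrame:
    """Per-phenotype paired t test across corresponding nodes.

    ``fractions_a``/``fractions_b`` give each node's cell fraction in the
    pooled group-A and group-B maps (same node ids); pairs are the nodes of
    one phenotype matched by id across the two maps.
    """
    phenotypes = pd.Series(dict(phenotypes)) if not isinstance(phenotypes, pd.Series) else phenotypes
    if not fractions_a.index.equals(fractions_b.index):
        raise ValueError("the two groups must share the same node id set")
    rows = []
    for phen, nodes in phenotypes.groupby(phenotypes).groups.items():
        a = fractions_a.reindex(pd.Index(nodes)).to_numpy(dtype=float)
        b = fractions_b.reindex(pd.Index(nodes)).to_numpy(dtype=float)
        if len(a) < 2:
            rows.append({"phenotype": phen, "n_nodes": len(a),
                         "t": np.nan, "p": np.nan, "defined": False})
            continue
        diff = a - b
        if np.allclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff.mean(), 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = np.sign(diff.mean()) * np.inf, 0.0
        else:
            t, p = stats.ttest_rel(a, b)
        rows.append({"phenotype": phen, "n_nodes": len(a),
                     "t": float(t), "p": float(p), "defined": True})
    return pd.DataFrame(rows).set_index("phenotype")


def z_ratio(
    marker_summary: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    cutoff: float = Z_RATIO_CUTOFF,
) -> pd.DataFrame:
    """Z-ratio differential activation statistic.

    Each feature is Z-scored across all samples in the comparison; per
    feature the difference d_i between group-mean Z scores is divided by the
    SD of all the d_j in this comparison.  |Z ratio| >= ``cutoff`` (1.96,
    the two-sided P < 0.05 normal critical value) is flagged significant.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 1 or len(group_b) < 1:
        raise ValueError("each group needs at least one sample")
    if marker_summary.shape[1] < 2:
        raise ValueError("the Z ratio needs at least 2 features")
    sub = marker_summary.loc[group_a + group_b]
    mean, sd = sub.mean(axis=0), sub.std(axis=0, ddof=1)
    z = (sub - mean).div(sd.replace(0.0, np.nan), axis=1).fillna(0.0)
    d = z.loc[group_a].mean(axis=0) - z.loc[group_b].mean(axis=0)
    sd_d = d.std(ddof=1)
    if not np.isfinite(sd_d) or sd_d == 0:
        raise ValueError("degenerate comparison: SD of mean-Z differences is 0")
    ratio = d / sd_d
    return pd.DataFrame(
        {"d": d, "z_ratio": ratio, "significant": ratio.abs() >= cutoff}
    ).rename_axis("feature")


def activation_summary(
    events: CellEventTable,
    nodes: ScaffoldNodeSet,
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample, per-phenotype mean activation-marker intensities.

    Each cell is mapped to its nearest node centroid in lineage-marker
    space and inherits that node's phenotype; activation markers are then
    averaged per (sample, phenotype).  Columns are ``phenotype:marker``;
    combinations absent in any sample are dropped so the result is a
    complete matrix suitable for :func:`z_ratio`.
    """
    if nodes.phenotypes is None:
        raise ValueError("nodes must be phenotype-annotated")
    if markers is None:
        markers = [m for m in events.markers if m not in LINEAGE_MARKERS]
    lineage = [m for m in LINEAGE_MARKERS if m in events.markers]
    from sklearn.metrics import pairwise_distances_argmin

    assign = pairwise_distances_argmin(
        events.data[lineage].to_numpy(dtype=float),
        nodes.medians[lineage].to_numpy(dtype=float),
    )
    phen = nodes.phenotypes.iloc[assign].to_numpy()
    df = events.data[[SAMPLE_COL, *markers]].copy()
    df["phenotype"] = phen
    wide = df.groupby([SAMPLE_COL, "phenotype"])[list(markers)].mean().unstack("phenotype")
    wide.columns = [f"{p}:{m}" for m, p in wide.columns]
    return wide.dropna(axis=1)


def exhausted_cd8_score(nodes: ScaffoldNodeSet) -> pd.Series:
    """Per-sample fraction of cells in partially exhausted CD8 nodes, the
    canonical orientation score for subtype labeling."""
    phen = nodes.phenotype_fractions()
    if EXHAUSTED_CD8 not in phen.columns:
        raise ValueError(f"no node labeled {EXHAUSTED_CD8!r}")
    return phen[EXHAUSTED_CD8]
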