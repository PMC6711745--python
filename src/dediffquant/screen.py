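"""Co-expression module detection and the three-factor regulator screen.

The screen nominates candidate transcriptional regulators of cell identity
by intersecting three criteria: membership in the co-expression module that
carries the majority of the AT1/AT2 marker genes, presence on a curated
transcription-factor list, and differential expression below a deliberately
permissive adjusted-p cutoff (default 0.2).

Module detection follows the weighted-network recipe: soft-thresholded
absolute Pearson correlation (adjacency |r|^beta), optional topological
overlap similarity, average-linkage hierarchical clustering and a static
tree cut, with undersized clusters dissolved into module 0 (unassigned).
The whole module is deterministic given its inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "ModuleAssignment",
    "filter_expressed",
    "adjacency_matrix",
    "tom_similarity",
    "coexpression_modules",
    "select_marker_module",
    "three_factor_screen",
]


@dataclass
class ModuleAssignment:
    """Gene -> module map (module 0 = unassigned) with per-module summaries."""

    modules: pd.Series  # index: gene id, values: int module id
    module_stats: pd.DataFrame  # per module id > 0: size, mean intra-module |cor|
    params: dict = field(default_factory=dict)

    def genes_in(self, module_id: int) -> pd.Index:
        return self.modules.index[self.modules == module_id]


def filter_expressed(matrix: pd.DataFrame, min_level: float = 40.0) -> pd.DataFrame:
    """Keep genes whose mean normalized count across samples exceeds ``min_level``.

    The boundary is strict (a mean of exactly ``min_level`` is dropped).
    Kept/dropped counts are recorded in ``result.attrs``.
    """
    keep = matrix.mean(axis=1) > min_level
    out = matrix[keep]
    if out.empty:
        raise ValueError(f"no gene passes the expression filter at min_level={min_level}")
    out.attrs["n_kept"] = int(keep.sum())
    out.attrs["n_dropped"] = int((~keep).sum())
    return out


def adjacency_matrix(matrix: pd.DataFrame, beta: float = 3.0, *, signed: bool = False) -> np.ndarray:
    """Soft-thresholded co-expression adjacency |cor|^beta (or signed variant)."""
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    if signed:
        a = ((1.0 + r) / 2.0) ** beta
    else:
        a = np.abs(r) ** beta
    a[sd == 0, :] = 0.0
    a[:, sd == 0] = 0.0
    np.fill_diagonal(a, 1.0)
    return a


def tom_similarity(a: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of a weighted adjacency matrix."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def coexpression_modules(
    matrix: pd.DataFrame,
    beta: float = 3.0,
    *,
    use_tom: bool = True,
    cut_height: float = 0.8,
    min_module_size: int = 10,
    signed: bool = False,
    reassign_by_kme: bool = True,
    kme_min: float = 0.4,
    merge_cor: float = 0.75,
    groups: pd.Series | None = None,
) -> ModuleAssignment:
    """Detect co-expression modules by soft-threshold network clustering.

    Dissimilarity is 1 - adjacency (or 1 - TOM when ``use_tom``), clustered
    by average linkage and cut at ``cut_height``; clusters smaller than
    ``min_module_size`` dissolve into module 0.  With ``reassign_by_kme``
    (default), membership is then consolidated by module eigengenes: every
    gene goes to the module whose eigengene it correlates with most
    strongly, provided |kME| >= ``kme_min``, and to module 0 otherwise.
    This rescues genes a static tree cut narrowly drops and sheds weakly
    attached ones.  Module ids are assigned in decreasing final size order,
    so module 1 is always the largest.  Constant genes are assigned module
    0 with a warning.  The whole procedure is deterministic.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation networks")
    if matrix.shape[0] < min_module_size:
        raise ValueError("fewer genes than min_module_size")
    work = matrix
    if groups is not None:
        # center each gene within sample groups so the network reflects
        # co-variation rather than the treatment contrast; otherwise module
        # membership preferentially recruits genes with chance group shifts
        work = matrix.copy()
        for g in pd.unique(groups):
            cols = groups.index[groups == g]
            cols = [c for c in cols if c in work.columns]
            work[cols] = work[cols].sub(work[cols].mean(axis=1), axis=0) + matrix.mean(axis=1).to_numpy()[:, None]
    sd = work.to_numpy(dtype=float).std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} constant genes assigned to module 0")
    a = adjacency_matrix(work, beta, signed=signed)
    sim = tom_similarity(a) if use_tom else a
    dis = 1.0 - sim
    np.fill_diagonal(dis, 0.0)
    dis = (dis + dis.T) / 2.0
    link = average(squareform(dis, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")
    raw[sd == 0] = 0

    sizes = pd.Series(raw[raw > 0]).value_counts()
    keep = sizes[sizes >= min_module_size].index
    labels = np.where(np.isin(raw, keep), raw, 0)

    if labels.max() > 0:
        labels = _merge_close_modules(work.to_numpy(dtype=float), labels, merge_cor)
    if reassign_by_kme and labels.max() > 0:
        labels = _kme_reassign(work.to_numpy(dtype=float), labels, kme_min, min_module_size)

    # relabel by final size, largest first, for stable module ids
    final_sizes = pd.Series(labels[labels > 0]).value_counts()
    order = final_sizes.sort_values(ascending=False).index
    remap = {old: new for new, old in enumerate(order, start=1)}
    modules = pd.Series(
        [remap.get(c, 0) for c in labels], index=matrix.index, name="module", dtype=int
    )

    with np.errstate(invalid="ignore"):
        r = np.nan_to_num(np.corrcoef(work.to_numpy(dtype=float)), nan=0.0)
    stats_rows = []
    for mid in sorted(set(modules) - {0}):
        sel = (modules == mid).to_numpy()
        sub = np.abs(r[np.ix_(sel, sel)])
        n = sel.sum()
        mean_cor = (sub.sum() - n) / (n * (n - 1)) if n > 1 else np.nan
        stats_rows.append({"module": mid, "size": int(n), "mean_intra_abs_cor": float(mean_cor)})
    stats = pd.DataFrame(stats_rows).set_index("module") if stats_rows else pd.DataFrame(
        columns=["size", "mean_intra_abs_cor"]
    )
    params = dict(
        beta=beta, use_tom=use_tom, cut_height=cut_height,
        min_module_size=min_module_size, signed=signed,
        reassign_by_kme=reassign_by_kme, kme_min=kme_min, merge_cor=merge_cor,
        group_centered=groups is not None,
    )
    return ModuleAssignment(modules=modules, module_stats=stats, params=params)


def _module_eigengenes(x: np.ndarray, labels: np.ndarray) -> tuple[list[int], np.ndarray]:
    """Leading principal component per module on standardized expression,
    oriented to correlate positively with the module's average profile."""
    sd = x.std(axis=1)
    z = np.zeros_like(x)
    ok = sd > 0
    z[ok] = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    mids = sorted(set(labels[labels > 0]))
    eig = []
    for mid in mids:
        sub = z[labels == mid]
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        e = vt[0]
        if (sub @ e).sum() < 0:
            e = -e
        eig.append(e)
    return mids, np.asarray(eig)


def _merge_close_modules(x: np.ndarray, labels: np.ndarray, merge_cor: float) -> np.ndarray:
    """Merge modules whose eigengenes correlate above ``merge_cor``.

    Fragments of one underlying module share the latent signal driving it,
    so their eigengenes are nearly collinear; distinct modules are not.
    Iterates on the closest pair until no pair qualifies (deterministic;
    the surviving id is the smaller of the two).
    """
    labels = labels.copy()
    while True:
        mids, eig = _module_eigengenes(x, labels)
        if len(mids) < 2:
            return labels
        c = np.corrcoef(eig)
        np.fill_diagonal(c, -np.inf)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if c[i, j] <= merge_cor:
            return labels
        keep, drop = sorted((mids[i], mids[j]))
        labels[labels == drop] = keep


def _kme_reassign(
    x: np.ndarray, labels: np.ndarray, kme_min: float, min_module_size: int
) -> np.ndarray:
    """Consolidate module membership by eigengene correlation (kME).

    The eigengene of a module is the leading principal component of its
    standardized gene expression, oriented to correlate positively with the
    module on average.  Each gene joins the module maximizing |kME|, if that
    exceeds ``kme_min``; modules falling below ``min_module_size`` after
    reassignment dissolve.
    """
    sd = x.std(axis=1)
    z = np.zeros_like(x)
    ok = sd > 0
    z[ok] = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    mids = sorted(set(labels[labels > 0]))
    eig = []
    for mid in mids:
        sub = z[labels == mid]
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        e = vt[0]
        if (sub @ e).sum() < 0:  # orient toward the module's average profile
            e = -e
        eig.append(e / np.linalg.norm(e))
    eig = np.asarray(eig)
    n = x.shape[1]
    kme = np.zeros((x.shape[0], len(mids)))
    for j in range(len(mids)):
        e = eig[j]
        ez = (e - e.mean()) / e.std()
        kme[:, j] = z @ ez / n
    best = np.argmax(np.abs(kme), axis=1)
    best_val = np.abs(kme)[np.arange(x.shape[0]), best]
    new = np.where((best_val >= kme_min) & ok, np.asarray(mids)[best], 0)
    sizes = pd.Series(new[new > 0]).value_counts()
    small = sizes[sizes < min_module_size].index
    new = np.where(np.isin(new, small), 0, new)
    return new


def select_marker_module(
    assignment: ModuleAssignment, marker_sets: dict[str, frozenset[str] | set[str]]
) -> tuple[int, pd.DataFrame]:
    """Pick the module holding the most combined marker-set members.

    ``marker_sets`` maps set names (e.g. AT1/AT2) to gene-id sets.  Returns
    the winning module id and a per-module marker-count table (modules in
    rows, one column per marker set plus totals).  Ties resolve to the
    lower module id and are flagged in ``table.attrs["tie"]``.
    """
    modules = assignment.modules
    mids = sorted(set(modules) - {0})
    rows = []
    for mid in mids:
        genes = set(assignment.genes_in(mid))
        row = {"module": mid, "size": len(genes)}
        for name, members in marker_sets.items():
            row[f"n_{name}"] = len(genes & set(members))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("module")
    count_cols = [c for c in table.columns if c.startswith("n_")]
    table["n_markers_total"] = table[count_cols].sum(axis=1)
    if table.empty or table["n_markers_total"].max() == 0:
        raise ValueError("no marker-set member is assigned to any module")
    best = table["n_markers_total"].max()
    winners = table.index[table["n_markers_total"] == best]
    table.attrs["tie"] = len(winners) > 1
    return int(winners.min()), table


def three_factor_screen(
    assignment: ModuleAssignment,
    marker_module_id: int,
    tf_list: list[str] | set[str],
    de_result: pd.DataFrame,
    adjp_cutoff: float = 0.2,
) -> pd.DataFrame:
    """Intersect module membership, TF annotation and differential expression.

    A gene passes when it sits in the marker-bearing module, appears on the
    TF list and has DE adjp below ``adjp_cutoff``.  The full audit table is
    returned for every gene in the union of the three inputs, with passing
    genes sorted first by adjp.
    """
    tf_set = set(tf_list)
    in_module = set(assignment.genes_in(marker_module_id))
    universe = sorted(set(assignment.modules.index) | tf_set | set(de_result.index))
    adjp = de_result["adjp"] if "adjp" in de_result else pd.Series(dtype=float)
    tab = pd.DataFrame(index=pd.Index(universe, name="gene_id"))
    tab["in_marker_module"] = [g in in_module for g in universe]
    tab["is_tf"] = [g in tf_set for g in universe]
    tab["de_adjp"] = [float(adjp.get(g, np.nan)) for g in universe]
    tab["passes_all"] = (
        tab["in_marker_module"] & tab["is_tf"] & (tab["de_adjp"] < adjp_cutoff)
    )
    tab = tab.sort_values(["passes_all", "de_adjp"], ascending=[False, True])
    tab.attrs["adjp_cutoff"] = adjp_cutoff
    tab.attrs["marker_module_id"] = marker_module_id
    return tab
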