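"""Marker application: band matrices, discrimination statistics, genetic
distance and UPGMA clustering.

Band matrices are varieties × markers with entries in {0, 1, missing} — the
binary gel score of each marker lane. Genetic distance defaults to the
simple-matching distance (fraction of pairwise-comparable markers at which
two varieties differ); Jaccard distance (mismatches over markers where at
least one variety shows the 1-band) is available as an option. Clustering is
average-linkage UPGMA with lexicographic tie-breaking, emitted as newick.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

MISSING = "."


@dataclass
class BandMatrix:
    """Binary band scores: float frame (0.0/1.0/NaN), varieties in rows."""

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.groups.index):
            raise DesignError("band matrix and group labels index mismatch")
        vals = self.data.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DesignError(
                f"band matrix entry at variety {self.data.index[i]!r}, "
                f"marker {self.data.columns[j]!r} outside {{0,1,missing}}"
            )

    @property
    def varieties(self) -> list[str]:
        return list(self.data.index)

    @property
    def markers(self) -> list[str]:
        return list(self.data.columns)


def read_band_matrix(path: str | os.PathLike) -> BandMatrix:
    """Read the band-matrix TSV dialect: columns ``variety``, ``group``, then
    one column per marker with entries 0, 1 or ``.`` (missing)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("variety", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: band matrix lacks a {col!r} column")
    marker_cols = [c for c in df.columns if c not in ("variety", "group")]
    data = {}
    for col in marker_cols:
        vals = []
        for row_i, raw in enumerate(df[col]):
            s = str(raw).strip()
            if s == MISSING or s == "nan":
                vals.append(np.nan)
            elif s in ("0", "1"):
                vals.append(float(s))
            else:
                raise FormatError(
                    f"{path}: invalid entry {raw!r} at variety "
                    f"{df['variety'][row_i]!r}, marker {col!r} "
                    "(expected 0, 1 or '.')"
                )
        data[col] = vals
    frame = pd.DataFrame(data, index=df["variety"].tolist())
    frame.index.name = "variety"
    groups = pd.Series(df["group"].tolist(), index=frame.index, name="group")
    return BandMatrix(data=frame, groups=groups)


def write_band_matrix(matrix: BandMatrix, path: str | os.PathLike) -> None:
    out = matrix.data.copy()
    out = out.map(lambda x: MISSING if pd.isna(x) else str(int(x)))
    out.insert(0, "group", matrix.groups)
    out.insert(0, "variety", matrix.data.index)
    out.to_csv(path, sep="\t", index=False)


def discrimination_report(matrix: BandMatrix) -> tuple[pd.DataFrame, dict]:
    """Per-marker discrimination calls and a panel summary.

    A marker discriminates when its non-missing entries are constant within
    each group and the two group values differ. ``out_of_group_carriers``
    lists varieties whose band equals the *other* group's modal band (the
    "indica varieties harbouring the javanica allele" phenomenon).
    """
    labels = sorted(matrix.groups.unique())
    if len(labels) != 2:
        raise DesignError(f"expected exactly two groups, got {labels}")
    a, b = labels
    rows = []
    for marker in matrix.markers:
        col = matrix.data[marker]
        col_a = col[matrix.groups == a].dropna()
        col_b = col[matrix.groups == b].dropna()
        if col_a.empty and col_b.empty:
            rows.append({"marker": marker, "status": "uninformative",
                         "out_of_group_carriers": ""})
            continue
        vals_a, vals_b = set(col_a), set(col_b)
        discriminating = (len(vals_a) == 1 and len(vals_b) == 1
                          and vals_a != vals_b)
        modal_a = col_a.mode().iloc[0] if not col_a.empty else np.nan
        modal_b = col_b.mode().iloc[0] if not col_b.empty else np.nan
        carriers = []
        if not pd.isna(modal_a) and not pd.isna(modal_b) and modal_a != modal_b:
            carriers += list(col_a[col_a == modal_b].index)
            carriers += list(col_b[col_b == modal_a].index)
        rows.append(
            {
                "marker": marker,
                "status": "discriminating" if discriminating else "not_discriminating",
                "out_of_group_carriers": ",".join(carriers),
            }
        )
    report = pd.DataFrame(rows, columns=["marker", "status", "out_of_group_carriers"])
    n_inf = int((report["status"] != "uninformative").sum())
    n_disc = int((report["status"] == "discriminating").sum())
    summary = {
        "n_markers": len(matrix.markers),
        "n_uninformative": len(matrix.markers) - n_inf,
        "n_discriminating": n_disc,
        "fraction_discriminating": n_disc / n_inf if n_inf else 0.0,
    }
    return report, summary


def genetic_distance(
    matrix: BandMatrix,
    method: str = "simple_matching",
    strict: bool = False,
) -> pd.DataFrame:
    """Pairwise genetic distance in [0, 1] over pairwise-complete markers.

    ``simple_matching``: mismatches / comparable markers. ``jaccard``:
    mismatches / markers where at least one of the pair shows a band.
    Pairs with zero comparable markers get NaN (error when ``strict``).
    """
    if method not in ("simple_matching", "jaccard"):
        raise DesignError(f"unknown distance method {method!r}")
    x = matrix.data.to_numpy(dtype=float)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(x[i]) & ~np.isnan(x[j])
            xi, xj = x[i][both], x[j][both]
            if method == "jaccard":
                keep = (xi == 1) | (xj == 1)
                xi, xj = xi[keep], xj[keep]
            if xi.size == 0:
                if strict:
                    raise DesignError(
                        f"no comparable markers between "
                        f"{matrix.varieties[i]!r} and {matrix.varieties[j]!r}"
                    )
                d[i, j] = d[j, i] = np.nan
            else:
                d[i, j] = d[j, i] = float(np.mean(xi != xj))
    return pd.DataFrame(d, index=matrix.varieties, columns=matrix.varieties)


def _fmt_branch(x: float) -> str:
    return f"{x:.6g}"


def upgma_tree(distances: pd.DataFrame) -> str:
    """Rooted UPGMA tree as a newick string with branch lengths.

    Average linkage on the full distance matrix; at each step the pair of
    clusters with the smallest average distance merges, ties broken by the
    lexicographically smallest pair of cluster name-tuples (so output is
    deterministic). Node height is half the merge distance.
    """
    if distances.isna().to_numpy().any():
        raise DesignError("distance matrix contains missing values")
    if not np.allclose(distances.to_numpy(), distances.to_numpy().T):
        raise DesignError("distance matrix is not symmetric")
    names = list(distances.index)
    if len(names) < 2:
        raise DesignError("need at least two varieties for a tree")

    # cluster id -> (member-name tuple, size, height, newick fragment)
    clusters: dict[int, tuple[tuple[str, ...], int, float, str]] = {
        i: ((name,), 1, 0.0, name) for i, name in enumerate(names)
    }
    dist: dict[tuple[int, int], float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            dist[(i, j)] = float(distances.iloc[i, j])
    next_id = len(names)
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((clusters[kv[0][0]][0],
                                                 clusters[kv[0][1]][0])))),
        )
        (ci, cj), dij = best
        mem_i, size_i, h_i, nwk_i = clusters[ci]
        mem_j, size_j, h_j, nwk_j = clusters[cj]
        height = dij / 2.0
        left, right = sorted(
            [(mem_i, h_i, nwk_i), (mem_j, h_j, nwk_j)], key=lambda t: t[0]
        )
        nwk = (
            f"({left[2]}:{_fmt_branch(height - left[1])},"
            f"{right[2]}:{_fmt_branch(height - right[1])})"
        )
        merged = (tuple(sorted(mem_i + mem_j)), size_i + size_j, height, nwk)
        # average-linkage update against every remaining cluster
        for ck in list(clusters):
            if ck in (ci, cj):
                continue
            d_ik = dist.pop((min(ci, ck), max(ci, ck)))
            d_jk = dist.pop((min(cj, ck), max(cj, ck)))
            dist[(min(next_id, ck), max(next_id, ck))] = (
                (size_i * d_ik + size_j * d_jk) / (size_i + size_j)
            )
        del dist[(ci, cj)]
        del clusters[ci], clusters[cj]
        clusters[next_id] = merged
        next_id += 1
    (_, _, _, nwk), = clusters.values()
    return nwk + ";"


def mean_group_distances(
    distances: pd.DataFrame, groups: pd.Series
) -> tuple[float, float]:
    """(mean within-group, mean between-group) distance over all pairs."""
    within, between = [], []
    names = list(distances.index)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = distances.iloc[i, j]
            if groups[names[i]] == groups[names[j]]:
                within.append(d)
            else:
                between.append(d)
    return (float(np.mean(within)) if within else float("nan"),
            float(np.mean(between)) if between else float("nan"))
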