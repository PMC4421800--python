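"""miRNA family and cluster evolution analysis.

Homologous miRNA genes are grouped by name: a family collects loci that
share a base name after stripping the trailing numeric copy suffix
(miR-19b-1, miR-19b-2) and the single-letter paralog suffix (miR-92a,
miR-92b).  From per-species locus tables the module derives copy-number
tables (single- vs multi-copy fractions over the conserved families),
detects genomic clusters by single-linkage chaining of neighbouring
precursors, computes mixed-case consensus sequences of homolog groups,
and builds neighbour-joining trees from p-distance matrices with
bootstrap support over alignment columns.

The NJ implementation is the canonical agglomeration and therefore
recovers the generating topology and branch lengths exactly on
additive distance matrices.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_NAME_RE = re.compile(
    r"^(?:(?P<species>[a-z]{3,4})-)?(?P<prefix>mir|let|miR|lin)-?(?P<num>\d+)"
    r"(?P<paralog>[a-z]+)?(?:-(?P<copy>\d+))?(?:-(?P<arm>[35]p))?$",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class MirnaLocus:
    species: str
    name: str
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str = "+"

    @property
    def family(self) -> str:
        return parse_family(self.name)


def parse_family(name: str) -> str:
    """Family base name of a precursor: species prefix dropped, copy
    and paralog suffixes stripped, case normalized (mir-92a-1 ->
    miR-92).  Unparseable names pass through with a warning."""
    m = _NAME_RE.match(name.strip())
    if not m:
        warnings.warn(f"unparseable miRNA name {name!r}; using it verbatim as family")
        return name
    prefix = m.group("prefix").lower()
    prefix = "miR" if prefix == "mir" else prefix
    return f"{prefix}-{m.group('num')}"


def copy_number_table(loci_by_species: dict[str, list[MirnaLocus]]) -> pd.DataFrame:
    """Family copy counts per species, plus single/multi-copy fractions.

    A family is conserved when present in at least two species; the
    summary fractions are computed over a species' conserved families.
    """
    fam_counts: dict[str, dict[str, int]] = {}
    for sp, loci in loci_by_species.items():
        fam_counts[sp] = {}
        for locus in loci:
            fam = locus.family
            fam_counts[sp][fam] = fam_counts[sp].get(fam, 0) + 1
    presence: dict[str, int] = {}
    for sp, fams in fam_counts.items():
        for fam in fams:
            presence[fam] = presence.get(fam, 0) + 1
    rows = []
    for sp in sorted(fam_counts):
        conserved = {f: c for f, c in fam_counts[sp].items() if presence[f] >= 2}
        n = len(conserved)
        multi = sum(1 for c in conserved.values() if c > 1)
        rows.append(
            {
                "species": sp,
                "n_families": len(fam_counts[sp]),
                "n_conserved_families": n,
                "n_multi_copy": multi,
                "single_copy_fraction": (n - multi) / n if n else float("nan"),
                "multi_copy_fraction": multi / n if n else float("nan"),
                "max_copies": max(conserved.values(), default=0),
            }
        )
    return pd.DataFrame(rows)


def family_copy_counts(loci: list[MirnaLocus]) -> pd.Series:
    counts: dict[str, int] = {}
    for locus in loci:
        counts[locus.family] = counts.get(locus.family, 0) + 1
    return pd.Series(dict(sorted(counts.items())), dtype=int)


@dataclass
class Cluster:
    contig: str
    members: list[MirnaLocus]

    @property
    def span(self) -> int:
        return max(m.end for m in self.members) - min(m.start for m in self.members)


def detect_clusters(loci: list[MirnaLocus], max_gap: int = 10_000) -> list[Cluster]:
    """Single-linkage chaining: consecutive precursors on one contig
    within ``max_gap`` nt (end to next start) join one cluster."""
    by_contig: dict[str, list[MirnaLocus]] = {}
    for locus in loci:
        by_contig.setdefault(locus.contig, []).append(locus)
    clusters = []
    for contig in sorted(by_contig):
        members = sorted(by_contig[contig], key=lambda m: (m.start, m.end, m.name))
        cur = [members[0]]
        cur_end = members[0].end
        for m in members[1:]:
            if m.start - cur_end <= max_gap:
                cur.append(m)
                cur_end = max(cur_end, m.end)
            else:
                clusters.append(Cluster(contig, cur))
                cur = [m]
                cur_end = m.end
        clusters.append(Cluster(contig, cur))
    return clusters


def consensus(seqs: list[str], case_threshold: float = 0.9) -> str:
    """Per-position modal base of equal-length homologs, uppercase when
    the modal frequency reaches ``case_threshold``; ties break by
    fixed base order (A < C < G < U)."""
    if not seqs:
        raise ValueError("empty input")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length (pre-aligned)")
    use_u = any("U" in s.upper() or "u" in s for s in seqs)
    order = "ACGU"
    out = []
    for i in range(lengths.pop()):
        col = [s[i].upper().replace("T", "U") for s in seqs]
        col = [c for c in col if c in order]
        if not col:
            out.append("-")
            continue
        counts = {b: col.count(b) for b in order}
        modal = max(order, key=lambda b: (counts[b], -order.index(b)))
        freq = counts[modal] / len(col)
        base = modal if use_u else modal.replace("U", "T")
        out.append(base if freq >= case_threshold else base.lower())
    return "".join(out)


# ---------------------------------------------------------------------------
# distances, neighbour joining, bootstrap


def p_distance_matrix(aligned: dict[str, str]) -> pd.DataFrame:
    """Pairwise p-distance (mismatches / compared sites) with pairwise
    deletion of gap columns."""
    names = list(aligned)
    n = len(names)
    arr = np.array([list(aligned[k].upper().replace("U", "T")) for k in names])
    gap = (arr == "-") | (arr == ".") | (arr == "N")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            if not ok.any():
                raise ValueError(f"no comparable sites between {names[i]} and {names[j]}")
            d[i, j] = d[j, i] = (arr[i][ok] != arr[j][ok]).mean()
    return pd.DataFrame(d, index=names, columns=names)


class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []  # (child, branch length)

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._nwk()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"

    def leaves(self) -> frozenset:
        if not self.children:
            return frozenset([self.name])
        out = frozenset()
        for c, _ in self.children:
            out |= c.leaves()
        return out


def nj_tree(dist: pd.DataFrame) -> "_Node":
    """Neighbour joining on a symmetric distance matrix (>= 3 taxa).

    Returns an unrooted tree (trifurcating root node); on an additive
    matrix the generating topology and branch lengths are recovered
    exactly.
    """
    d = dist.to_numpy(dtype=float, copy=True)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    if d.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [_Node(str(name)) for name in dist.index]
    active = list(range(len(nodes)))
    dm = {(i, j): d[i, j] for i in range(len(nodes)) for j in range(len(nodes))}
    nxt = len(nodes)
    while len(active) > 3:
        r = {i: sum(dm[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (len(active) - 2) * dm[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        m = len(active) - 2
        bi = 0.5 * dm[i, j] + (r[i] - r[j]) / (2 * m)
        bj = dm[i, j] - bi
        parent = _Node(children=[(nodes[i], bi), (nodes[j], bj)])
        nodes.append(parent)
        for k in active:
            if k in (i, j):
                continue
            dm[nxt, k] = dm[k, nxt] = 0.5 * (dm[i, k] + dm[j, k] - dm[i, j])
        dm[nxt, nxt] = 0.0
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    i, j, k = active
    bi = 0.5 * (dm[i, j] + dm[i, k] - dm[j, k])
    bj = 0.5 * (dm[i, j] + dm[j, k] - dm[i, k])
    bk = 0.5 * (dm[i, k] + dm[j, k] - dm[i, j])
    return _Node(children=[(nodes[i], bi), (nodes[j], bj), (nodes[k], bk)])


def tree_bipartitions(root: "_Node") -> set[frozenset]:
    """Non-trivial bipartitions, each as the smaller-side leaf set of an
    internal edge (canonical min-side encoding)."""
    all_leaves = root.leaves()
    splits = set()

    def walk(node):
        for child, _ in node.children:
            if child.children:
                side = child.leaves()
                other = all_leaves - side
                if len(side) >= 2 and len(other) >= 2:
                    splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
            walk(child)

    walk(root)
    return splits


def bootstrap_support(
    aligned: dict[str, str], n_replicates: int = 1000, seed: int = 0
) -> dict[frozenset, float]:
    """Column-resampling bootstrap support of the NJ tree's internal
    bipartitions; deterministic under a fixed seed."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    base = nj_tree(p_distance_matrix(aligned))
    target = tree_bipartitions(base)
    if not target:
        return {}
    rng = np.random.default_rng(seed)
    L = len(next(iter(aligned.values())))
    names = list(aligned)
    arr = {k: np.array(list(v)) for k, v in aligned.items()}
    hits = {s: 0 for s in target}
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = {k: "".join(arr[k][cols]) for k in names}
        try:
            splits = tree_bipartitions(nj_tree(p_distance_matrix(rep)))
        except ValueError:  # a pair with no comparable sites resampled
            continue
        for s in target:
            if s in splits:
                hits[s] += 1
    return {s: hits[s] / n_replicates for s in target}


def random_additive_tree(n_taxa: int, rng) -> tuple["_Node", pd.DataFrame]:
    """A random binary tree with positive branch lengths plus its exact
    additive leaf-to-leaf distance matrix (for round-trip checks and
    simulation)."""
    names = [f"t{i + 1}" for i in range(n_taxa)]
    nodes = [_Node(nm) for nm in names]
    roots = list(range(n_taxa))
    nxt = n_taxa
    while len(roots) > 2:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        a, b = roots[i], roots[j]
        ba = round(float(rng.uniform(0.05, 1.0)), 3)
        bb = round(float(rng.uniform(0.05, 1.0)), 3)
        nodes.append(_Node(children=[(nodes[a], ba), (nodes[b], bb)]))
        roots = [r for k, r in enumerate(roots) if k not in (i, j)] + [nxt]
        nxt += 1
    a, b = roots
    bl = round(float(rng.uniform(0.05, 1.0)), 3)
    root = _Node(children=[(nodes[a], bl / 2), (nodes[b], bl / 2)])
    # leaf-to-leaf distances via recursion
    dmat = pd.DataFrame(0.0, index=names, columns=names)

    def fill(node):
        if not node.children:
            return {node.name: 0.0}
        sides = []
        for child, blen in node.children:
            sub = fill(child)
            sides.append({k: v + blen for k, v in sub.items()})
        for x in range(len(sides)):
            for y in range(x + 1, len(sides)):
                for na, da in sides[x].items():
                    for nb, db in sides[y].items():
                        dmat.loc[na, nb] = dmat.loc[nb, na] = da + db
        merged = {}
        for s in sides:
            merged.update(s)
        return merged

    fill(root)
    return root, dmat
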