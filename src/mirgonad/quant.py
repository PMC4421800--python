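"""Expression, differential expression and biogenesis statistics.

Counts are normalized to reads per million (RPM) against each library's
clean-read total.  Two-library differential expression uses the exact
conditional-binomial test for two Poisson rates (the appropriate exact
test for deeply sequenced count libraries without replicates), with
Benjamini-Hochberg adjustment across rows and fold changes computed on
RPM with a small pseudocount.  Biogenesis summaries cover stage
specificity, isomiR composition (5'/3' offsets and non-templated 3'
additions relative to the precursor), length-resolved first-nucleotide
bias and per-precursor arm usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .align import canonical_dna


def rpm_normalize(counts: pd.DataFrame, totals: dict[str, int]) -> pd.DataFrame:
    """Scale each count column to reads per million of its library.

    When the matrix tabulates all clean reads of a library, its RPM
    column sums to exactly 1e6.
    """
    out = counts.astype(float).copy()
    for col in counts.columns:
        if totals[col] <= 0:
            raise ValueError(f"library total for {col!r} must be > 0")
        out[col] = counts[col] * 1e6 / totals[col]
    return out


def exact_count_test(a: int, b: int, total_a: int, total_b: int) -> float:
    """Two-sided exact test that two library counts share one rate.

    Conditional on a + b, the first count is Binomial(a + b,
    total_a / (total_a + total_b)) under the null; the p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    """
    n = a + b
    if n == 0:
        return 1.0
    p0 = total_a / (total_a + total_b)
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    return float(min(1.0, pmf[pmf <= pmf[a] * (1 + 1e-9)].sum()))


def diff_expression(
    counts: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    totals: dict[str, int],
    pseudocount_rpm: float = 0.01,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-row fold change, exact p-value and BH-adjusted p-value.

    Rows are flagged up/down in ``stage_a`` relative to ``stage_b``
    when |log2 FC| >= ``lfc_threshold`` and adjusted p < ``alpha``.
    """
    rpm = rpm_normalize(counts[[stage_a, stage_b]], totals)
    fc = (rpm[stage_a] + pseudocount_rpm) / (rpm[stage_b] + pseudocount_rpm)
    pvals = np.array(
        [
            exact_count_test(int(ca), int(cb), totals[stage_a], totals[stage_b])
            for ca, cb in zip(counts[stage_a], counts[stage_b])
        ]
    )
    padj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
    log2fc = np.log2(fc)
    out = pd.DataFrame(
        {
            f"rpm_{stage_a}": rpm[stage_a],
            f"rpm_{stage_b}": rpm[stage_b],
            "fold_change": fc,
            "log2_fc": log2fc,
            "p_value": pvals,
            "p_adj": padj,
        },
        index=counts.index,
    )
    out["direction"] = "ns"
    out.loc[(out["log2_fc"] >= lfc_threshold) & (out["p_adj"] < alpha), "direction"] = "up"
    out.loc[(out["log2_fc"] <= -lfc_threshold) & (out["p_adj"] < alpha), "direction"] = "down"
    return out


def specificity_class(rpm_row, threshold: float = 1.0) -> str:
    """Which stages express this row: a single stage name, a '+'-joined
    pair, 'all', or 'none' for an all-zero row."""
    present = [s for s in rpm_row.index if rpm_row[s] >= threshold and rpm_row[s] > 0]
    if not present:
        return "none"
    if len(present) == len(rpm_row.index):
        return "all"
    return "+".join(present)


def specificity_table(rpm: pd.DataFrame, threshold: float = 1.0) -> pd.Series:
    return pd.Series(
        {idx: specificity_class(rpm.loc[idx], threshold) for idx in rpm.index}, name="class"
    )


# ---------------------------------------------------------------------------
# isomiR and arm bookkeeping


@dataclass
class PrecursorRecord:
    """A named precursor with per-arm mature intervals (precursor-local,
    0-based half-open)."""

    precursor_id: str
    sequence: str
    arms: dict[str, tuple[int, int]]


@dataclass
class IsomirAssignment:
    parent: str  # "<precursor_id>:<arm>"
    tag_id: str
    off5: int
    off3: int
    nta: str
    counts: dict[str, int]


@dataclass
class IsomirSet:
    parent: str
    members: list[IsomirAssignment] = field(default_factory=list)

    @property
    def representative(self) -> IsomirAssignment:
        return min(self.members, key=lambda m: (-sum(m.counts.values()), m.tag_id))

    def variants(self, stage: str | None = None) -> set[tuple[int, int, str]]:
        out = set()
        for m in self.members:
            if stage is None or m.counts.get(stage, 0) > 0:
                out.add((m.off5, m.off3, m.nta))
        return out


def assign_tags_to_precursors(
    tags,
    precursors: list[PrecursorRecord],
    off5_max: int = 2,
    off3_max: int = 4,
    nta_max: int = 2,
) -> tuple[list[IsomirAssignment], int]:
    """Assign tags to precursor arms as isomiR variants.

    A tag matches when, after stripping up to ``nta_max`` trailing
    non-templated bases, its remainder occurs verbatim in a precursor
    with its 5' end within ``off5_max`` and its 3' end within
    ``off3_max`` of an annotated mature arm.  Templated parses are
    preferred over non-templated ones.  Returns the assignments and the
    number of unassignable tags.
    """
    blob_parts = []
    offsets = []  # (blob offset, record)
    off = 0
    for rec in precursors:
        seq = canonical_dna(rec.sequence)
        blob_parts.append(seq)
        offsets.append((off, rec, seq))
        off += len(seq) + 1
    blob = "#".join(blob_parts)
    assignments = []
    unassigned = 0
    for tag in tags:
        seq = canonical_dna(tag.sequence)
        placed = False
        for nta_len in range(0, nta_max + 1):
            core = seq[: len(seq) - nta_len] if nta_len else seq
            if len(core) < 12:
                break
            p = blob.find(core)
            while p >= 0 and not placed:
                for boff, rec, rseq in offsets:
                    if boff <= p < boff + len(rseq):
                        local = p - boff
                        for arm, (a0, a1) in sorted(rec.arms.items()):
                            off5 = local - a0
                            off3 = (local + len(core)) - a1
                            if abs(off5) <= off5_max and -off3_max <= off3 <= off3_max:
                                nta = seq[len(core) :]
                                # a true NTA base must not be templated
                                if nta and rseq[local + len(core) : local + len(core) + 1] == nta[:1]:
                                    continue
                                assignments.append(
                                    IsomirAssignment(
                                        f"{rec.precursor_id}:{arm}",
                                        tag.tag_id,
                                        off5,
                                        off3,
                                        nta,
                                        dict(tag.counts),
                                    )
                                )
                                placed = True
                                break
                        break
                if placed:
                    break
                p = blob.find(core, p + 1)
            if placed:
                break
        if not placed:
            unassigned += 1
    return assignments, unassigned


def isomir_sets(assignments) -> dict[str, IsomirSet]:
    out: dict[str, IsomirSet] = {}
    for a in assignments:
        out.setdefault(a.parent, IsomirSet(a.parent)).members.append(a)
    return out


def isomir_stats(
    tags, precursors, stages, off5_max: int = 2, off3_max: int = 4, nta_max: int = 2
) -> tuple[dict[str, IsomirSet], pd.Series, int]:
    """IsomiR sets per parent plus the per-stage mean isomiR count.

    The per-stage mean is (distinct isomiRs observed in the stage) /
    (parents observed in the stage), the standard "isomiRs per miRNA"
    summary.
    """
    assignments, unassigned = assign_tags_to_precursors(
        tags, precursors, off5_max, off3_max, nta_max
    )
    sets = isomir_sets(assignments)
    means = {}
    for stage in stages:
        n_var = sum(len(s.variants(stage)) for s in sets.values())
        n_parents = sum(1 for s in sets.values() if s.variants(stage))
        means[stage] = n_var / n_parents if n_parents else 0.0
    return sets, pd.Series(means, name="mean_isomirs"), unassigned


def first_nt_bias(tags, stages, by_reads: bool = True) -> dict[str, pd.DataFrame]:
    """Per-stage length x {A, C, G, U} first-nucleotide frequency.

    Computed on read counts by default (``by_reads=False`` switches to
    unique tags); every populated row sums to 1.
    """
    out = {}
    for stage in stages:
        acc: dict[int, dict[str, float]] = {}
        for tag in tags:
            w = tag.counts.get(stage, 0) if by_reads else int(tag.counts.get(stage, 0) > 0)
            if w == 0:
                continue
            first = canonical_dna(tag.sequence)[0].replace("T", "U")
            if first not in "ACGU":
                continue
            row = acc.setdefault(len(tag.sequence), {b: 0.0 for b in "ACGU"})
            row[first] += w
        df = pd.DataFrame.from_dict(acc, orient="index").sort_index()
        df = df.div(df.sum(axis=1), axis=0)
        out[stage] = df[list("ACGU")] if len(df) else pd.DataFrame(columns=list("ACGU"))
    return out


def length_distribution(tags, stages) -> pd.DataFrame:
    rows: dict[int, dict[str, int]] = {}
    for tag in tags:
        row = rows.setdefault(len(tag.sequence), {s: 0 for s in stages})
        for s in stages:
            row[s] += tag.counts.get(s, 0)
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def arm_usage(assignments) -> pd.DataFrame:
    """Per-precursor arm label (5p / 3p / both) and guide/star call.

    The guide arm is the more abundant one; equal totals are reported
    as co-dominant.
    """
    per_arm: dict[str, dict[str, int]] = {}
    for a in assignments:
        pid, arm = a.parent.rsplit(":", 1)
        per_arm.setdefault(pid, {})
        per_arm[pid][arm] = per_arm[pid].get(arm, 0) + sum(a.counts.values())
    rows = []
    for pid in sorted(per_arm):
        arms = per_arm[pid]
        expressed = sorted(a for a, c in arms.items() if c > 0)
        label = expressed[0] if len(expressed) == 1 else "both"
        c5, c3 = arms.get("5p", 0), arms.get("3p", 0)
        if c5 == c3:
            guide = "co-dominant"
        else:
            guide = "5p" if c5 > c3 else "3p"
        rows.append(
            {"precursor_id": pid, "label": label, "guide": guide,
             "reads_5p": c5, "reads_3p": c3}
        )
    return pd.DataFrame(rows)
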