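"""Census of Dip1-bound linear-filament pointed ends.

In TIRF assays, filaments nucleated by Dip1-activated Arp2/3 complex carry a
labeled Dip1 on their pointed end, so counting decorated vs total linear
pointed ends measures the fraction of filaments produced through the Dip1
pathway.  Because Wsp1-VCA roughly halves spontaneous nucleation, counts from
VCA-containing reactions are corrected by scaling the spontaneous
(undecorated) count before forming the percentage:

    percent_bound = 100 * bound / (bound + c * (total - bound))

with c = 2 for Wsp1-VCA conditions and c = 1 otherwise.  The same statistic
can be predicted from the kinetic model as the share of Dip1-origin barbed
ends among all ends at the census time point (150 s).

Group comparisons follow the field's convention: a two-tailed two-sample
t-test for two groups, one-way ANOVA with Tukey's HSD for more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from arpsyn import reaction_model as rm

#: Census time point: 2 min 30 s into the polymerization reaction.
CENSUS_TIME_S = 150.0

#: Default spontaneous-count correction when a Wsp1 VCA construct is present
#: (VCA constructs inhibit spontaneous nucleation about twofold).
VCA_CORRECTION = 2.0


@dataclass
class CensusRow:
    """One replicate's pointed-end counts under one condition."""

    replicate_id: str
    condition_id: str
    bound: int
    total: int
    correction: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.bound <= self.total):
            raise ValueError("need 0 <= bound <= total")
        if self.correction < 1.0:
            raise ValueError("correction factor must be >= 1")


@dataclass
class CensusTable:
    """Replicate counts of Dip1-bound and total linear pointed ends."""

    rows: list[CensusRow]
    conditions: dict[str, dict] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"replicate_id": r.replicate_id, "condition_id": r.condition_id,
             "bound": r.bound, "total": r.total, "correction": r.correction}
            for r in self.rows
        ])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CensusTable":
        df = pd.read_csv(path, sep="\t")
        rows = [
            CensusRow(str(r.replicate_id), str(r.condition_id),
                      int(r.bound), int(r.total), float(r.correction))
            for r in df.itertuples(index=False)
        ]
        return cls(rows)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def percent_bound(row: CensusRow) -> float:
    """Corrected percentage of linear pointed ends decorated by Dip1.

    The correction factor scales only the spontaneous (undecorated) count;
    decorated ends are taken to be Dip1-nucleated.
    """
    if row.total == 0:
        raise ValueError("total pointed-end count is zero")
    spont = row.total - row.bound
    return 100.0 * row.bound / (row.bound + row.correction * spont)


def percent_bound_by_condition(table: CensusTable) -> pd.DataFrame:
    """Per-condition mean +/- SEM of the corrected bound percentage."""
    df = table.to_frame()
    df["percent_bound"] = [percent_bound(r) for r in table]
    out = df.groupby("condition_id")["percent_bound"].agg(["mean", "sem", "count"])
    return out.rename(columns={"count": "n"}).reset_index()


def predict_percent_bound(
    net: rm.ReactionNetwork,
    initial: dict[str, float],
    t: float = CENSUS_TIME_S,
) -> float:
    """Model-predicted share of Dip1-origin ends at the census time (percent)."""
    grid = np.array([0.0, t / 2.0, t])
    res = rm.simulate(net, initial, grid)
    e_dip = float(res.ends_dip1[-1])
    e_spont = float(res.ends_spontaneous[-1])
    total = e_dip + e_spont
    if total <= 0:
        raise ValueError(f"no ends present at t={t} s")
    return 100.0 * e_dip / total


@dataclass
class GroupComparison:
    """Result of a two-group t-test or multi-group ANOVA + Tukey HSD."""

    test: str                      # "t-test" | "anova-tukey"
    statistic: float               # t or F
    p_value: float                 # test-level p (ANOVA p for >2 groups)
    pairwise: pd.DataFrame         # group_a, group_b, statistic, p_adj


def compare_groups(groups: dict[str, np.ndarray]) -> GroupComparison:
    """Compare replicate values across conditions.

    Two groups: two-tailed Student's t-test.  More: one-way ANOVA with
    Tukey's post-hoc pairwise adjustment.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two replicates")

    if len(arrays) == 2:
        t, p = stats.ttest_ind(arrays[0], arrays[1])
        pair = pd.DataFrame([{
            "group_a": names[0], "group_b": names[1],
            "statistic": float(t), "p_adj": float(p),
        }])
        return GroupComparison("t-test", float(t), float(p), pair)

    f, p = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "statistic": float(tukey.statistic[i, j]),
                "p_adj": float(tukey.pvalue[i, j]),
            })
    return GroupComparison("anova-tukey", float(f), float(p), pd.DataFrame(rows))


def census_report(table: CensusTable) -> dict:
    """Per-condition summary plus pairwise tests, as a JSON-ready dict."""
    summary = percent_bound_by_condition(table)
    df = table.to_frame()
    df["percent_bound"] = [percent_bound(r) for r in table]
    groups = {
        cond: grp["percent_bound"].to_numpy()
        for cond, grp in df.groupby("condition_id")
    }
    report = {"conditions": summary.to_dict(orient="records")}
    if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
        cmp = compare_groups(groups)
        report["test"] = cmp.test
        report["statistic"] = cmp.statistic
        report["p_value"] = cmp.p_value
        report["pairwise"] = cmp.pairwise.to_dict(orient="records")
    return report
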