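"""Dataset-level analysis: group statistics, ROC thresholds and classification.

The central object is :class:`MethylationStudy`, a model built from a
manifest of methylation instances (enzyme, structure, site, methylation type,
orientation, REBASE-derived effect group) plus the corresponding structures.
Construction grafts every methyl and records all near contacts once; fitting
at a given coordinate-uncertainty allowance is then pure arithmetic, which
makes the allowance sweep cheap.  ``fit()`` returns a :class:`StudyResults`
carrying per-enzyme scores, Wilcoxon rank-sum comparisons between effect
groups, Shapiro-Wilk normality checks, ROC curves with AUC for each clash
measure, and threshold classification at the published operating points
(most severe distance clash with the protein > 1.1 A, cumulative volume
overlap with the protein > 47.7 A^3).

Group labels are externally supplied experimental annotations; they are never
inferred from the scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skmetrics

from .clash import (ClashParams, MethylClashSummary, distance_clash,
                    find_contacts, sphere_overlap_volume)
from .grafting import graft_methyl
from .radii import METHYL_RADIUS, RadiusTable
from .structure import PartnerCategory, StructureComplex

MEASURES = ("max_delta_d", "sum_delta_d", "max_delta_V", "sum_delta_V",
            "n_contacts", "n_residues")

#: decision thresholds of the published predictors (protein partners only)
DEFAULT_THRESHOLDS = {"max_delta_d": 1.1, "sum_delta_V": 47.7}

GROUPS = ("cognate_protective", "noncognate_tolerated", "noncognate_protective")

_PROTEIN = {PartnerCategory.PROTEIN_MAIN_CHAIN.value,
            PartnerCategory.PROTEIN_SIDE_CHAIN.value}


@dataclass
class MethylationInstance:
    """One methylation case of the study manifest."""

    enzyme: str
    structure_id: str
    site: Tuple[str, int]
    methyl_type: str
    orientation: str = "trans"
    group: str = "unknown"
    notes: str = ""


@dataclass
class EnzymeScore:
    """Per-enzyme aggregated clash measures."""

    enzyme: str
    values: Dict[str, float] = field(default_factory=dict)
    n_asu_copies: int = 1
    n_strands: int = 1
    strand: Optional[str] = None


# --------------------------------------------------------------------------
# statistical primitives


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value (H0: same distribution).

    Exact enumeration when both samples have <= 10 observations and the
    pooled data are tie-free; otherwise the normal approximation with tie
    correction (no continuity correction, so identical groups give p = 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and a.size <= 10 and b.size <= 10:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    return float(res.pvalue)


def normality_test(values: Sequence[float]) -> float:
    """Shapiro-Wilk p-value (H0: drawn from a normal distribution)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for a constant sample")
    return float(stats.shapiro(x).pvalue)


def roc_curve(scores: Sequence[float], labels: Sequence[bool]
              ) -> Tuple[List[Tuple[float, float]], float]:
    """Threshold-parameterized ROC points (FPR, TPR) and trapezoid AUC.

    ``labels`` marks protective (positive) cases; ties in scores are grouped.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.size == 0 or y.min() == y.max():
        raise ValueError("ROC needs both protective and tolerated cases")
    fpr, tpr, _ = _skmetrics.roc_curve(y, s, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_skmetrics.auc(fpr, tpr))


def classify_protection(score, measure: str = "max_delta_d",
                        threshold: Optional[float] = None) -> str:
    """Predict "protective" iff the clash score strictly exceeds the threshold.

    ``score`` may be a number, an :class:`EnzymeScore` or a mapping.  The
    measure is understood to be computed against protein partners only.
    """
    if threshold is None:
        if measure not in DEFAULT_THRESHOLDS:
            raise ValueError(f"no default threshold for measure {measure!r}; "
                             f"defaults exist for {sorted(DEFAULT_THRESHOLDS)}")
        threshold = DEFAULT_THRESHOLDS[measure]
    if isinstance(score, EnzymeScore):
        value = score.values[measure]
    elif isinstance(score, dict):
        value = score[measure]
    else:
        value = float(score)
    return "protective" if value > threshold else "tolerated"


def aggregate_enzyme(summaries: Sequence[MethylClashSummary],
                     policy: str = "mean_over_copies_and_strands",
                     enzyme: str = "",
                     strands: Optional[Sequence[str]] = None,
                     copies: Optional[Sequence] = None) -> List[EnzymeScore]:
    """Average per-methyl summaries into enzyme-level scores.

    ``mean_over_copies_and_strands`` returns a single score; with
    ``mean_over_copies_strands_separate`` the two strands are kept apart
    (one score per strand, averaged over ASU copies within each).
    """
    if not summaries:
        raise ValueError("cannot aggregate an empty list of summaries")
    if policy not in ("mean_over_copies_and_strands",
                      "mean_over_copies_strands_separate"):
        raise ValueError(f"unknown aggregation policy {policy!r}")
    strands = list(strands) if strands is not None else ["?"] * len(summaries)
    copies = list(copies) if copies is not None else [1] * len(summaries)
    frame = pd.DataFrame([s.as_dict() for s in summaries])
    frame["strand"] = strands
    frame["copy"] = copies
    if policy == "mean_over_copies_and_strands":
        values = frame[list(MEASURES)].mean()
        return [EnzymeScore(enzyme=enzyme, values=values.to_dict(),
                            n_asu_copies=frame["copy"].nunique(),
                            n_strands=frame["strand"].nunique())]
    out = []
    for strand, sub in frame.groupby("strand", sort=True):
        values = sub[list(MEASURES)].mean()
        out.append(EnzymeScore(enzyme=enzyme, values=values.to_dict(),
                               n_asu_copies=sub["copy"].nunique(),
                               n_strands=1, strand=str(strand)))
    return out


# --------------------------------------------------------------------------
# model


def _lens_volume_vec(r: np.ndarray, d: np.ndarray, R: float = METHYL_RADIUS
                     ) -> np.ndarray:
    out = np.array([sphere_overlap_volume(R, ri, di) for ri, di in zip(r, d)])
    return out


class MethylationStudy:
    """Clash-score study over a manifest of methylation instances.

    Parameters
    ----------
    contacts : DataFrame
        One row per (instance, nearby partner atom): columns ``instance_id``,
        ``D`` (measured distance, A), ``r`` (partner radius, A), ``category``,
        ``element``, ``partner_chain``, ``partner_resid``, ``partner_resname``,
        ``partner_atom``, ``is_methyl_methyl``.
    instances : DataFrame
        One row per methylation instance: ``instance_id``, ``enzyme``,
        ``structure_id``, ``chain``, ``resid``, ``methyl_type``,
        ``orientation``, ``group``, ``strand``, ``asu_copy``.
    """

    def __init__(self, contacts: pd.DataFrame, instances: pd.DataFrame):
        self.contacts = contacts.reset_index(drop=True)
        self.instances = instances.reset_index(drop=True)
        missing = set(self.instances.instance_id) - set(self.contacts.instance_id)
        # instances with no near contacts at all are legal (all-zero scores)
        self._contactless = sorted(missing)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_complexes(cls, manifest: pd.DataFrame,
                       complexes: Dict[str, StructureComplex],
                       params: Optional[ClashParams] = None,
                       table: Optional[RadiusTable] = None) -> "MethylationStudy":
        """Graft and collect near contacts for every manifest row.

        The manifest needs columns enzyme, structure_id, chain, resid,
        methyl_type; optional columns orientation (default trans), group
        (default unknown), asu_copy (default 1) and
        strand_partner_methylated (default False; when true, methyls grafted
        on other rows of the same structure become eligible partners).
        """
        params = params or ClashParams()
        manifest = manifest.copy()
        for col, default in (("orientation", "trans"), ("group", "unknown"),
                             ("asu_copy", 1), ("strand_partner_methylated", False)):
            if col not in manifest.columns:
                manifest[col] = default
        grafted = {}
        skipped = []
        for idx, row in manifest.iterrows():
            complex_ = complexes.get(row.structure_id)
            if complex_ is None:
                skipped.append((idx, f"structure {row.structure_id} not provided"))
                continue
            target = complex_.find_residue(str(row.chain), int(row.resid))
            if target is None:
                skipped.append((idx, f"{row.structure_id}: no residue "
                                     f"{row.chain}/{row.resid}"))
                continue
            grafted[idx] = graft_methyl(target, row.methyl_type, row.orientation)
        if skipped:
            import logging
            for idx, why in skipped:
                logging.getLogger(__name__).warning("manifest row %s skipped: %s", idx, why)

        contact_rows = []
        instance_rows = []
        for idx, methyl in grafted.items():
            row = manifest.loc[idx]
            others = []
            if bool(row.strand_partner_methylated):
                others = [g for j, g in grafted.items()
                          if j != idx and manifest.loc[j].structure_id == row.structure_id]
            instance_id = f"{row.structure_id}:{row.chain}{row.resid}:{row.methyl_type}"
            instance_rows.append({
                "instance_id": instance_id, "enzyme": row.enzyme,
                "structure_id": row.structure_id, "chain": row.chain,
                "resid": int(row.resid), "methyl_type": row.methyl_type,
                "orientation": row.orientation, "group": row.group,
                "strand": str(row.chain), "asu_copy": row.asu_copy,
                "superposition_rmsd": methyl.superposition_rmsd,
            })
            for c in find_contacts(methyl, complexes[row.structure_id],
                                   params, others, table):
                res = c.partner.residue
                contact_rows.append({
                    "instance_id": instance_id, "D": c.D, "r": c.r,
                    "category": c.category.value, "element": c.element,
                    "partner_chain": res.chain_id if res else "",
                    "partner_resid": res.seq_id if res else -1,
                    "partner_resname": res.name if res else "",
                    "partner_atom": c.partner.name,
                    "is_methyl_methyl": c.is_methyl_methyl,
                })
        contacts = pd.DataFrame(contact_rows, columns=[
            "instance_id", "D", "r", "category", "element", "partner_chain",
            "partner_resid", "partner_resname", "partner_atom", "is_methyl_methyl"])
        instances = pd.DataFrame(instance_rows)
        if instances.empty:
            raise ValueError("no manifest row could be resolved to a structure site")
        return cls(contacts, instances)

    # -- scoring -----------------------------------------------------------

    def scores(self, epsilon: float = 0.1) -> pd.DataFrame:
        """Per-instance clash measures at a given allowance.

        Returns one row per instance with all-partner measures and their
        protein-only counterparts (columns prefixed ``protein_``), merged
        with the instance metadata.
        """
        c = self.contacts.copy()
        if len(c):
            c["delta_d"] = METHYL_RADIUS + c["r"] - (c["D"] + epsilon)
            c = c[c["delta_d"] > 0].copy()
            c["delta_V"] = _lens_volume_vec(c["r"].to_numpy(),
                                            (c["D"] + epsilon).to_numpy())
        rows = []
        for instance_id, meta in self.instances.set_index("instance_id").iterrows():
            sub = c[c["instance_id"] == instance_id] if len(c) else c
            row = dict(meta)
            row["instance_id"] = instance_id
            for prefix, part in (("", sub),
                                 ("protein_", sub[sub["category"].isin(_PROTEIN)]
                                  if len(sub) else sub)):
                if len(part):
                    row[prefix + "max_delta_d"] = float(part["delta_d"].max())
                    row[prefix + "sum_delta_d"] = float(part["delta_d"].sum())
                    row[prefix + "max_delta_V"] = float(part["delta_V"].max())
                    row[prefix + "sum_delta_V"] = float(part["delta_V"].sum())
                    row[prefix + "n_contacts"] = int(len(part))
                    row[prefix + "n_residues"] = int(part.groupby(
                        ["partner_chain", "partner_resid", "partner_resname"]
                    ).ngroups)
                else:
                    for m in MEASURES:
                        row[prefix + m] = 0.0 if "delta" in m else 0
            rows.append(row)
        return pd.DataFrame(rows)

    def enzyme_scores(self, epsilon: float = 0.1,
                      policy: str = "mean_over_copies_and_strands",
                      scope: str = "all") -> pd.DataFrame:
        """Enzyme-level scores: equal weight per enzyme, ASU copies averaged.

        scope "all" uses every partner; "protein" restricts to protein atoms
        (the predictor inputs).  Policy as in :func:`aggregate_enzyme`.
        """
        prefix = "protein_" if scope == "protein" else ""
        per_methyl = self.scores(epsilon)
        cols = [prefix + m for m in MEASURES]
        keys = ["enzyme", "group"]
        if policy == "mean_over_copies_strands_separate":
            keys = keys + ["strand"]
        elif policy != "mean_over_copies_and_strands":
            raise ValueError(f"unknown aggregation policy {policy!r}")
        agg = per_methyl.groupby(keys, sort=True)[cols].mean().reset_index()
        agg.columns = keys + list(MEASURES)
        return agg

    # -- fitting -----------------------------------------------------------

    def fit(self, epsilon: float = 0.1,
            policy: str = "mean_over_copies_and_strands",
            roc_level: str = "enzyme") -> "StudyResults":
        """Run the group comparisons, ROC analysis and threshold classification."""
        enzyme_all = self.enzyme_scores(epsilon, policy, scope="all")
        # classification always uses per-strand, ASU-averaged, protein-only
        # scores; an enzyme protected on both strands is judged by its
        # stronger strand
        strand_protein = self.enzyme_scores(
            epsilon, "mean_over_copies_strands_separate", scope="protein")
        enzyme_protein = (strand_protein
                          .groupby(["enzyme", "group"], sort=True)[list(MEASURES)]
                          .max().reset_index())

        tests = []
        comparisons = [("cognate_protective", "noncognate_tolerated"),
                       ("noncognate_protective", "noncognate_tolerated"),
                       ("cognate_protective", "noncognate_protective")]
        for ga, gb in comparisons:
            a = enzyme_all[enzyme_all.group == ga]
            b = enzyme_all[enzyme_all.group == gb]
            if len(a) < 2 or len(b) < 2:
                continue
            for m in MEASURES:
                tests.append({"group_a": ga, "group_b": gb, "measure": m,
                              "p_value": rank_sum_test(a[m], b[m])})
        group_tests = pd.DataFrame(tests)

        shapiro_rows = []
        for group, sub in enzyme_all.groupby("group"):
            for m in MEASURES:
                vals = sub[m].to_numpy(dtype=float)
                if len(vals) >= 3 and np.ptp(vals) > 0:
                    shapiro_rows.append({"group": group, "measure": m,
                                         "p_value": normality_test(vals)})
        shapiro = pd.DataFrame(shapiro_rows)

        roc_frame = (enzyme_protein if roc_level == "enzyme" else strand_protein)
        pos = roc_frame.group == "cognate_protective"
        neg = roc_frame.group == "noncognate_tolerated"
        rocs: Dict[str, dict] = {}
        if pos.sum() >= 1 and neg.sum() >= 1:
            sub = roc_frame[pos | neg]
            labels = (sub.group == "cognate_protective").to_numpy()
            for m in MEASURES:
                points, auc = roc_curve(sub[m].to_numpy(dtype=float), labels)
                rocs[m] = {"points": points, "auc": auc}

        classification = enzyme_protein.copy()
        for m, threshold in DEFAULT_THRESHOLDS.items():
            classification[f"pred_{m}"] = [
                classify_protection(v, m, threshold) for v in classification[m]]

        return StudyResults(
            model=self, epsilon=epsilon, policy=policy,
            enzyme_scores=enzyme_all, enzyme_protein_scores=enzyme_protein,
            strand_protein_scores=strand_protein,
            group_tests=group_tests, shapiro=shapiro, rocs=rocs,
            classification=classification,
        )

    def allowance_sweep(self, epsilons: Sequence[float] = (0.1, 0.2, 0.3, 0.4),
                        measures: Sequence[str] = MEASURES,
                        comparison: Tuple[str, str] = ("cognate_protective",
                                                       "noncognate_tolerated"),
                        policy: str = "mean_over_copies_and_strands"
                        ) -> pd.DataFrame:
        """Wilcoxon p-values per (allowance, measure): robustness of the split."""
        rows = []
        for eps in epsilons:
            enzymes = self.enzyme_scores(eps, policy)
            a = enzymes[enzymes.group == comparison[0]]
            b = enzymes[enzymes.group == comparison[1]]
            for m in measures:
                rows.append({"epsilon": eps, "measure": m,
                             "p_value": rank_sum_test(a[m], b[m])})
        return pd.DataFrame(rows)


def allowance_sweep(study: MethylationStudy,
                    epsilons: Sequence[float] = (0.1, 0.2, 0.3, 0.4),
                    measures: Sequence[str] = MEASURES, **kwargs) -> pd.DataFrame:
    """Module-level convenience wrapper around :meth:`MethylationStudy.allowance_sweep`."""
    return study.allowance_sweep(epsilons, measures, **kwargs)


# --------------------------------------------------------------------------
# results


@dataclass
class StudyResults:
    """Fitted study: scores, tests, ROC curves and classification."""

    model: MethylationStudy
    epsilon: float
    policy: str
    enzyme_scores: pd.DataFrame
    enzyme_protein_scores: pd.DataFrame
    strand_protein_scores: pd.DataFrame
    group_tests: pd.DataFrame
    shapiro: pd.DataFrame
    rocs: Dict[str, dict]
    classification: pd.DataFrame

    def auc(self, measure: str = "sum_delta_V") -> float:
        return self.rocs[measure]["auc"]

    def operating_point(self, measure: str,
                        threshold: Optional[float] = None) -> Dict[str, float]:
        """True/false positive rates of the threshold classifier.

        Positives = cognate protective enzymes, negatives = tolerated; the
        non-cognate protective group serves as validation (fraction predicted
        protective).
        """
        if threshold is None:
            threshold = DEFAULT_THRESHOLDS[measure]
        frame = self.enzyme_protein_scores
        def rate(group):
            sub = frame[frame.group == group]
            if not len(sub):
                return math.nan
            return float((sub[measure] > threshold).mean())
        return {
            "measure": measure, "threshold": threshold,
            "tp_rate": rate("cognate_protective"),
            "fp_rate": rate("noncognate_tolerated"),
            "validation_rate": rate("noncognate_protective"),
        }

    def validation_either_rate(self) -> float:
        """Fraction of non-cognate protective enzymes flagged by either predictor."""
        frame = self.enzyme_protein_scores
        sub = frame[frame.group == "noncognate_protective"]
        if not len(sub):
            return math.nan
        hit = np.zeros(len(sub), dtype=bool)
        for m, t in DEFAULT_THRESHOLDS.items():
            hit |= (sub[m] > t).to_numpy()
        return float(hit.mean())

    def summary(self) -> str:
        lines = []
        lines.append("Methylation clash study")
        lines.append("=" * 60)
        lines.append(f"allowance epsilon: {self.epsilon:.2f} A   "
                     f"aggregation: {self.policy}")
        counts = self.enzyme_scores.group.value_counts()
        lines.append("enzymes per group: " + ", ".join(
            f"{g}={counts.get(g, 0)}" for g in GROUPS))
        lines.append("")
        lines.append("Wilcoxon rank-sum tests (enzyme level, all partners)")
        lines.append("-" * 60)
        for (ga, gb), sub in self.group_tests.groupby(["group_a", "group_b"],
                                                      sort=False):
            lines.append(f"{ga} vs {gb}:")
            for _, row in sub.iterrows():
                lines.append(f"    {row.measure:<14} p = {row.p_value:.2e}")
        if self.rocs:
            lines.append("")
            lines.append("ROC (protein-only scores, per enzyme)")
            lines.append("-" * 60)
            for m in MEASURES:
                if m in self.rocs:
                    lines.append(f"    {m:<14} AUC = {self.rocs[m]['auc']:.3f}")
            for m in DEFAULT_THRESHOLDS:
                op = self.operating_point(m)
                lines.append(
                    f"    {m} > {op['threshold']}: TPR = {op['tp_rate']:.2f}, "
                    f"FPR = {op['fp_rate']:.2f}, "
                    f"validation = {op['validation_rate']:.2f}")
        return "\n".join(lines)

    def plot_roc(self, measures: Iterable[str] = ("max_delta_d", "sum_delta_V"),
                 ax=None):
        """ROC curves for the selected measures (requires matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for m in measures:
            if m not in self.rocs:
                continue
            pts = np.array(self.rocs[m]["points"])
            ax.plot(pts[:, 0], pts[:, 1],
                    label=f"{m} (AUC {self.rocs[m]['auc']:.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right")
        return ax
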