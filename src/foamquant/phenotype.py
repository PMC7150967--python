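"""Condition statistics, phenotype classification and wash-out reversibility.

Statistics follow the standard high-content design: per-cell measurements
are first averaged per well, and all inference runs on those replicate-level
means (never on individual cells, which would be pseudo-replication).  Each
feature gets a two-way ANOVA (condition × recovery time) and Bonferroni-
corrected pairwise t-tests of every treated condition against the untreated
control at the matched time point; significance means adjusted p < 0.05.

Phenotypes are called by a fixed-order decision list transcribing the
canonical signatures:

* ``pro_apoptotic`` — strong, significant cell shrinkage (≥2.5× down) with a
  collapsed vacuole count (≥4× down): apoptotic condensation.
* ``phospholipidosis`` — significantly changed vacuole count with an
  unchanged vacuole-occupied fraction (fewer-but-larger vacuoles) plus
  significant phospholipid accumulation (≥2× up).
* ``lipid_accumulating`` — morphology unchanged, only phospholipid content
  significantly elevated (≥1.5× up).
* ``normal`` — nothing significant.

Reversibility after stimulus wash-out is scored per feature with a recovery
index R = 1 − |recovered − baseline| / |acute − baseline| (clamped to [0,1]),
combined with the recovered-vs-baseline significance: ``reversible`` when
that contrast is non-significant and R ≥ 0.8, ``irreversible`` when it is
still significant and R < 0.2, ``partial`` otherwise, and ``not_applicable``
when there was no significant acute effect to recover from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .vacuoles import FEATURES

__all__ = [
    "StatsTable",
    "ClassifierThresholds",
    "PhenotypeCall",
    "compute_stats",
    "fold_changes",
    "classify_phenotype",
    "classify_all",
    "reversibility",
    "simulate_null_type1",
]

#: Features used for phenotype rules (subset of the full per-cell vector).
RULE_FEATURES = ["cell_area", "n_vacuoles", "vacuole_area_fraction", "phospholipid_total"]

_META = ["compound", "concentration_uM", "recovery_h"]
ALPHA = 0.05


@dataclass
class StatsTable:
    """ANOVA table and Bonferroni-adjusted pairwise contrasts per feature."""

    anova: pd.DataFrame  # feature, effect, F, p
    pairwise: pd.DataFrame  # feature, compound, concentration_uM, recovery_h, t, p_raw, p_adj, significant
    alpha: float = ALPHA

    def is_significant(
        self, feature: str, compound: str, concentration_uM: float, recovery_h: int
    ) -> bool:
        m = self.pairwise
        sel = m[
            (m["feature"] == feature)
            & (m["compound"].str.lower() == compound.lower())
            & (m["concentration_uM"] == float(concentration_uM))
            & (m["recovery_h"] == int(recovery_h))
        ]
        if sel.empty:
            raise KeyError(
                f"no contrast for {feature} / {compound} {concentration_uM} uM R{recovery_h}"
            )
        return bool(sel["significant"].iloc[0])


def _well_means(records: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    required = _META + ["experiment", "well"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"records lack metadata columns: {missing}")
    return records.groupby(_META + ["experiment", "well"], as_index=False)[features].mean()


def compute_stats(
    records: pd.DataFrame,
    features: list[str] | None = None,
    alpha: float = ALPHA,
    baseline_compound: str = "untreated",
) -> StatsTable:
    """ANOVA + Bonferroni pairwise contrasts on well-level means.

    ``records`` is the per-cell table with condition metadata.  Raises when
    any (condition, time) cell of the design has fewer than two replicate
    wells — a design on which neither the ANOVA nor the contrasts are
    estimable.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    features = features or [f for f in RULE_FEATURES if f in records.columns]
    wm = _well_means(records, features)
    wm = wm.copy()
    wm["condition"] = (
        wm["compound"].str.lower() + "_" + wm["concentration_uM"].map("{:g}".format)
    )

    counts = wm.groupby(["condition", "recovery_h"]).size()
    deficient = counts[counts < 2]
    if len(deficient):
        cells = ", ".join(f"{c} R{r} (n={n})" for (c, r), n in deficient.items())
        raise ValueError(f"<2 replicate wells in design cell(s): {cells}")

    anova_rows, pair_rows = [], []
    base = wm[wm["compound"].str.lower() == baseline_compound]
    if base.empty:
        raise ValueError(f"baseline compound {baseline_compound!r} absent from records")
    treated_keys = (
        wm.loc[wm["compound"].str.lower() != baseline_compound, ["compound", "concentration_uM"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    treated_keys = list(treated_keys)

    for feat in features:
        two_way = wm["recovery_h"].nunique() > 1 and wm["condition"].nunique() > 1
        if two_way:
            formula = f"{feat} ~ C(condition) * C(recovery_h)"
        elif wm["condition"].nunique() > 1:
            formula = f"{feat} ~ C(condition)"
        else:
            formula = f"{feat} ~ C(recovery_h)"
        fit = smf.ols(formula, data=wm).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        for effect, row in table.iterrows():
            if effect == "Residual":
                continue
            anova_rows.append(
                {"feature": feat, "effect": effect, "F": row["F"], "p": row["PR(>F)"]}
            )

        contrasts = []
        for key in treated_keys:
            for rec in sorted(wm["recovery_h"].unique()):
                t_vals = wm.loc[
                    (wm["compound"] == key.compound)
                    & (wm["concentration_uM"] == key.concentration_uM)
                    & (wm["recovery_h"] == rec),
                    feat,
                ]
                b_vals = base.loc[base["recovery_h"] == rec, feat]
                if t_vals.empty or b_vals.empty:
                    continue
                t, p = sps.ttest_ind(t_vals, b_vals, equal_var=True)
                contrasts.append((key.compound, key.concentration_uM, rec, t, p))
        m = len(contrasts)
        for compound, conc, rec, t, p in contrasts:
            p_adj = min(1.0, p * m)
            pair_rows.append(
                {
                    "feature": feat,
                    "compound": compound,
                    "concentration_uM": conc,
                    "recovery_h": rec,
                    "t": t,
                    "p_raw": p,
                    "p_adj": p_adj,
                    "significant": p_adj < alpha,
                }
            )

    return StatsTable(
        anova=pd.DataFrame(anova_rows),
        pairwise=pd.DataFrame(pair_rows),
        alpha=alpha,
    )


def fold_changes(
    summary: pd.DataFrame,
    baseline_compound: str = "untreated",
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Treated/untreated fold changes within matched recovery time points.

    ``fold`` is treated mean / baseline mean; ``direction`` is up/down/none
    (a <2% departure counts as none), and ``fold_magnitude`` expresses the
    change the way effect sizes are usually quoted: x-times higher for
    increases, x-times fewer (baseline/treated) for decreases.  Zero baseline
    means yield NaN folds with ``undefined_baseline`` flagged.
    """
    features = features or [f for f in RULE_FEATURES if f + "_mean" in summary.columns]
    is_base = summary["compound"].str.lower() == baseline_compound
    base = summary[is_base].set_index("recovery_h")
    if base.empty:
        raise ValueError(f"baseline compound {baseline_compound!r} absent at every time point")
    rows = []
    for _, row in summary[~is_base].iterrows():
        rec = row["recovery_h"]
        if rec not in base.index:
            raise ValueError(f"baseline missing at recovery_h={rec}")
        for feat in features:
            b = float(base.loc[rec, f"{feat}_mean"])
            t = float(row[f"{feat}_mean"])
            undefined = b == 0
            fold = np.nan if undefined else t / b
            if undefined or abs(fold - 1) < 0.02:
                direction, mag = "none", 1.0 if not undefined else np.nan
            elif fold > 1:
                direction, mag = "up", fold
            else:
                direction, mag = "down", 1.0 / fold
            rows.append(
                {
                    "compound": row["compound"],
                    "concentration_uM": row["concentration_uM"],
                    "recovery_h": rec,
                    "feature": feat,
                    "treated_mean": t,
                    "baseline_mean": b,
                    "fold": fold,
                    "direction": direction,
                    "fold_magnitude": mag,
                    "undefined_baseline": undefined,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Effect-size cut-offs of the phenotype decision list (fold units)."""

    apoptotic_area_fold_down: float = 2.5
    apoptotic_vacuole_fold_down: float = 4.0
    phospholipidosis_phos_fold_up: float = 2.0
    lipid_phos_fold_up: float = 1.5


@dataclass
class PhenotypeCall:
    compound: str
    concentration_uM: float
    label: str  # normal | phospholipidosis | pro_apoptotic | lipid_accumulating
    rule_trace: list[str] = field(default_factory=list)
    decided_at_recovery_h: int | None = None


_PRIORITY = ["pro_apoptotic", "phospholipidosis", "lipid_accumulating", "normal"]


def _rules_at_timepoint(
    f: dict[str, dict], sig: dict[str, bool], thr: ClassifierThresholds
) -> tuple[str, list[str]]:
    """Evaluate the decision list on one time point's folds/significances."""
    area, vac = f["cell_area"], f["n_vacuoles"]
    frac, phos = f["vacuole_area_fraction"], f["phospholipid_total"]
    if (
        area["direction"] == "down"
        and area["fold_magnitude"] >= thr.apoptotic_area_fold_down
        and sig["cell_area"]
        and vac["direction"] == "down"
        and vac["fold_magnitude"] >= thr.apoptotic_vacuole_fold_down
        and sig["n_vacuoles"]
    ):
        return "pro_apoptotic", [
            f"cell_area down {area['fold_magnitude']:.1f}x (significant)",
            f"n_vacuoles down {vac['fold_magnitude']:.1f}x (significant)",
        ]
    if (
        sig["n_vacuoles"]
        and not sig["vacuole_area_fraction"]
        and phos["direction"] == "up"
        and phos["fold_magnitude"] >= thr.phospholipidosis_phos_fold_up
        and sig["phospholipid_total"]
    ):
        return "phospholipidosis", [
            f"n_vacuoles changed {vac['fold_magnitude']:.1f}x {vac['direction']} (significant)",
            "vacuole_area_fraction unchanged (not significant)",
            f"phospholipid_total up {phos['fold_magnitude']:.1f}x (significant)",
        ]
    morpho_sig = sig["cell_area"] or sig["n_vacuoles"] or sig["vacuole_area_fraction"]
    if (
        not morpho_sig
        and sig["phospholipid_total"]
        and phos["direction"] == "up"
        and phos["fold_magnitude"] >= thr.lipid_phos_fold_up
    ):
        return "lipid_accumulating", [
            "morphometry unchanged (no significant contrast)",
            f"phospholipid_total up {phos['fold_magnitude']:.1f}x (significant)",
        ]
    return "normal", []


def classify_phenotype(
    folds: pd.DataFrame,
    stats: StatsTable,
    compound: str,
    concentration_uM: float,
    thresholds: ClassifierThresholds | None = None,
) -> PhenotypeCall:
    """Call the phenotype of one treated condition.

    The decision list is evaluated at each recovery time point (acute
    first); the overall label is the highest-priority non-normal call across
    time points — a pure function of (folds, stats, thresholds).
    """
    thr = thresholds or ClassifierThresholds()
    sel = folds[
        (folds["compound"].str.lower() == compound.lower())
        & (folds["concentration_uM"] == float(concentration_uM))
    ]
    if sel.empty:
        raise ValueError(f"no fold changes for {compound} {concentration_uM} uM")
    missing = set(RULE_FEATURES) - set(sel["feature"])
    if missing:
        raise ValueError(f"fold table lacks feature(s): {sorted(missing)}")

    best_label, best_trace, best_rec = "normal", [], None
    for rec in sorted(sel["recovery_h"].unique()):
        at = sel[sel["recovery_h"] == rec].set_index("feature")
        f = {feat: at.loc[feat].to_dict() for feat in RULE_FEATURES}
        sig = {
            feat: stats.is_significant(feat, compound, concentration_uM, rec)
            for feat in RULE_FEATURES
        }
        label, trace = _rules_at_timepoint(f, sig, thr)
        if _PRIORITY.index(label) < _PRIORITY.index(best_label):
            best_label = label
            best_trace = [f"R{rec}: {t}" for t in trace]
            best_rec = int(rec)
    return PhenotypeCall(
        compound=compound,
        concentration_uM=float(concentration_uM),
        label=best_label,
        rule_trace=best_trace,
        decided_at_recovery_h=best_rec,
    )


def classify_all(
    folds: pd.DataFrame,
    stats: StatsTable,
    thresholds: ClassifierThresholds | None = None,
) -> list[PhenotypeCall]:
    keys = folds[["compound", "concentration_uM"]].drop_duplicates()
    return [
        classify_phenotype(folds, stats, k.compound, k.concentration_uM, thresholds)
        for k in keys.itertuples(index=False)
    ]


def reversibility(
    summary: pd.DataFrame,
    stats: StatsTable,
    compound: str,
    concentration_uM: float,
    features: list[str] | None = None,
    baseline_compound: str = "untreated",
    recovered_at: int = 48,
) -> pd.DataFrame:
    """Per-feature recovery verdicts for one treated condition.

    The acute effect is the R0 treated-vs-baseline difference; recovery is
    judged at ``recovered_at`` (24 or 48 h wash-out) against the baseline at
    the same time point.  The recovery index R is invariant to affine
    rescaling of the feature.  Features with no significant acute effect are
    ``not_applicable``.
    """
    features = features or RULE_FEATURES
    sel = summary[
        (summary["compound"].str.lower() == compound.lower())
        & (summary["concentration_uM"] == float(concentration_uM))
    ].set_index("recovery_h")
    base = summary[summary["compound"].str.lower() == baseline_compound].set_index(
        "recovery_h"
    )
    for rec, frame, what in ((0, sel, compound), (recovered_at, sel, compound),
                             (0, base, baseline_compound), (recovered_at, base, baseline_compound)):
        if rec not in frame.index:
            raise ValueError(f"{what}: missing recovery_h={rec} time point")

    rows = []
    for feat in features:
        acute = float(sel.loc[0, f"{feat}_mean"])
        recov = float(sel.loc[recovered_at, f"{feat}_mean"])
        b0 = float(base.loc[0, f"{feat}_mean"])
        br = float(base.loc[recovered_at, f"{feat}_mean"])
        acute_sig = stats.is_significant(feat, compound, concentration_uM, 0)
        recov_sig = stats.is_significant(feat, compound, concentration_uM, recovered_at)
        denom = abs(acute - b0)
        if not acute_sig or denom == 0:
            verdict, r_index = "not_applicable", np.nan
        else:
            r_index = float(np.clip(1.0 - abs(recov - br) / denom, 0.0, 1.0))
            if not recov_sig and r_index >= 0.8:
                verdict = "reversible"
            elif recov_sig and r_index < 0.2:
                verdict = "irreversible"
            else:
                verdict = "partial"
        rows.append(
            {
                "compound": compound,
                "concentration_uM": float(concentration_uM),
                "feature": feat,
                "recovered_at_h": recovered_at,
                "acute_mean": acute,
                "recovered_mean": recov,
                "baseline_acute_mean": b0,
                "baseline_recovered_mean": br,
                "recovery_index": r_index,
                "verdict": verdict,
            }
        )
    df = pd.DataFrame(rows)
    verdicts = set(df["verdict"]) - {"not_applicable"}
    if not verdicts:
        overall = "not_applicable"
    elif verdicts == {"reversible"}:
        overall = "reversible"
    elif verdicts == {"irreversible"}:
        overall = "irreversible"
    else:
        overall = "mixed"
    df.attrs["overall"] = overall
    return df


def simulate_null_type1(
    n_sims: int = 1000,
    n_wells: int = 5,
    alpha: float = ALPHA,
    rng_seed: int = 0,
) -> float:
    """Empirical type-I error of the contrast path under the null.

    Simulates ``n_sims`` two-condition single-time designs whose well means
    share one normal distribution, runs :func:`compute_stats`, and returns
    the fraction with a significant treated-vs-untreated contrast.
    """
    rng = np.random.default_rng(rng_seed)
    hits = 0
    wells, compounds, exps = [], [], []
    for i in range(2 * n_wells):
        wells.append(f"W{i:02d}")
        compounds.append("untreated" if i < n_wells else "drug")
        exps.append(i % n_wells + 1)
    template = pd.DataFrame(
        {
            "well": wells,
            "compound": compounds,
            "concentration_uM": [0.0 if c == "untreated" else 1.0 for c in compounds],
            "recovery_h": 0,
            "experiment": exps,
        }
    )
    for _ in range(n_sims):
        df = template.copy()
        df["cell_area"] = rng.normal(size=len(df))
        st = compute_stats(df, features=["cell_area"], alpha=alpha)
        hits += int(st.pairwise["significant"].iloc[0])
    return hits / n_sims
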