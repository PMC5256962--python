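"""Multiple-testing adjustment, significance calls and report tables.

Benjamini-Hochberg adjustment is applied per coefficient family
(substrate; interaction) within each fraction, across proteins, matching
the per-effect reporting of the result tables; time main effects are
fitted but not FDR-reported unless requested.  A protein is called
significant when the substrate or the interaction coefficient reaches
q <= 0.01 (inclusive).  Supernatant calls are additionally filtered
against localization annotations: only proteins plausibly released in
the extracellular milieu (cellulosome, secreted, cell wall, cellulosomal
flag, or extracytoplasmic CAZymes) are retained, the rest being flagged
as lysis-derived.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "adjust_bh",
    "add_q_values",
    "call_significant",
    "classify_fraction_effects",
    "filter_supernatant",
    "go_profile_ratios",
    "export_report",
]

#: localization classes counted as extracellular for the lysis filter
EXTRACELLULAR_CLASSES = {"cellulosome", "secreted", "cell wall"}
EXTRACYTOPLASMIC_CLASSES = EXTRACELLULAR_CLASSES | {"membrane"}

#: coefficient families reported and FDR-adjusted by default
REPORTED_FAMILIES = ("alpha", "gamma")


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, capped at 1; tied p-values share a q-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def add_q_values(
    fits: pd.DataFrame, families: tuple[str, ...] = REPORTED_FAMILIES
) -> pd.DataFrame:
    """Attach q-values per (fraction, coefficient family) across proteins.

    Coefficients outside the reported families keep q = NaN.
    """
    out = fits.copy()
    out["q_value"] = np.nan
    for (fraction, coef), idx in out.groupby(["fraction", "coefficient"]).groups.items():
        if coef not in families:
            continue
        out.loc[idx, "q_value"] = adjust_bh(out.loc[idx, "p_value"].to_numpy())
    return out


def call_significant(
    effects: pd.DataFrame, q_threshold: float = 0.01
) -> pd.DataFrame:
    """Flag effects with q <= threshold (inclusive)."""
    out = effects.copy()
    out["significant"] = out["q_value"].notna() & (out["q_value"] <= q_threshold)
    return out


def significant_proteins(effects: pd.DataFrame, fraction: str | None = None) -> set[str]:
    """Proteins with at least one significant reported coefficient."""
    sub = effects if fraction is None else effects[effects["fraction"] == fraction]
    return set(sub.loc[sub["significant"], "protein_id"])


def classify_fraction_effects(
    pellet_significant: set[str], supernatant_significant: set[str]
) -> dict[str, int]:
    """Partition significant proteins by fraction membership."""
    both = pellet_significant & supernatant_significant
    return {
        "pellet-only": len(pellet_significant - both),
        "supernatant-only": len(supernatant_significant - both),
        "both": len(both),
    }


def filter_supernatant(
    proteins: set[str], annotations: pd.DataFrame
) -> tuple[set[str], set[str]]:
    """Split supernatant calls into extracellular-plausible and lysis-derived.

    A protein is retained when its localization class is cellulosome,
    secreted or cell wall, or it carries the cellulosomal flag, or it is
    a CAZyme with an extracytoplasmic localization.  Proteins without
    annotation are conservatively flagged as lysis-derived.

    ``annotations`` needs columns protein_id, localization, cazyme,
    cellulosomal.
    """
    ann = annotations.set_index("protein_id")
    retained, lysis = set(), set()
    for pid in proteins:
        if pid not in ann.index:
            lysis.add(pid)
            continue
        row = ann.loc[pid]
        loc = str(row["localization"]).lower()
        keep = (
            loc in EXTRACELLULAR_CLASSES
            or bool(row["cellulosomal"])
            or (bool(row["cazyme"]) and loc in EXTRACYTOPLASMIC_CLASSES)
        )
        (retained if keep else lysis).add(pid)
    return retained, lysis


def go_profile_ratios(
    annotations: pd.DataFrame,
    significant: set[str],
    min_significant_proteins: int | None = None,
) -> pd.DataFrame:
    """Per-GO-term enrichment ratios between significant and all proteins.

    For each term: the percentage of that term among the GO annotations
    of significant proteins, the percentage among the annotations of all
    proteins, and the ratio of both percentages.  Terms annotating fewer
    than ``min_significant_proteins`` significant proteins are dropped
    when the flag is set.  A term with no annotation in the genome-wide
    set would have an undefined ratio; such terms cannot occur here since
    the genome-wide set is the universe, but a zero-denominator guard
    flags them as NaN.

    ``annotations`` needs columns protein_id and go_terms (semicolon
    separated); proteins without terms contribute nothing.
    """
    pairs = []
    for _, row in annotations.iterrows():
        terms = [t for t in str(row.get("go_terms", "") or "").split(";") if t]
        for t in terms:
            pairs.append((row["protein_id"], t))
    if not pairs:
        return pd.DataFrame(columns=["go_term", "pct_significant", "pct_all", "ratio", "n_significant"])
    ann = pd.DataFrame(pairs, columns=["protein_id", "go_term"])
    total_all = len(ann)
    sig_ann = ann[ann["protein_id"].isin(significant)]
    total_sig = len(sig_ann)
    if total_sig == 0:
        return pd.DataFrame(columns=["go_term", "pct_significant", "pct_all", "ratio", "n_significant"])
    rows = []
    for term, grp in ann.groupby("go_term"):
        k_all = len(grp)
        sub = sig_ann[sig_ann["go_term"] == term]
        k_sig = len(sub)
        if k_sig == 0:
            continue
        pct_sig = 100.0 * k_sig / total_sig
        pct_all = 100.0 * k_all / total_all
        ratio = pct_sig / pct_all if pct_all > 0 else np.nan
        rows.append(
            {
                "go_term": term,
                "pct_significant": pct_sig,
                "pct_all": pct_all,
                "ratio": ratio,
                "n_significant": sub["protein_id"].nunique(),
            }
        )
    out = pd.DataFrame(rows)
    if min_significant_proteins is not None:
        out = out[out["n_significant"] >= min_significant_proteins]
    return out.sort_values("ratio", ascending=False, kind="stable").reset_index(drop=True)


def export_report(
    effects: pd.DataFrame, annotations: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Wide per-protein report of significant effects.

    One row per protein carrying at least one significant effect, with
    the log10 fold-change estimate in the matching cell (pellet/
    supernatant x substrate/interaction) and NaN elsewhere; positive
    values mean higher levels (substrate) or faster increase
    (interaction) on the non-reference substrate.
    """
    sig = effects[effects["significant"]]
    cols = [
        "pellet_substrate", "pellet_interaction",
        "supernatant_substrate", "supernatant_interaction",
    ]
    rows: dict[str, dict] = {}
    coef_name = {"alpha": "substrate", "gamma": "interaction"}
    for _, r in sig.iterrows():
        if r["coefficient"] not in coef_name:
            continue
        rows.setdefault(r["protein_id"], {c: np.nan for c in cols})
        rows[r["protein_id"]][f"{r['fraction']}_{coef_name[r['coefficient']]}"] = r["estimate"]
    report = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=cols)
    report.index.name = "protein_id"
    report = report.sort_index().reset_index()
    if annotations is not None:
        report = report.merge(annotations, on="protein_id", how="left")
    return report
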