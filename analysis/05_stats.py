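"""Association analysis: pattern groups vs demographics and risk factors.

Two parts: (a) the reference cohort's published cross-tabulations, re-tested
with the Fisher/chi-square dispatcher and the printed summary statistics
with the pooled t test; (b) the synthetic cohort's own group comparison,
logistic association model with diagnostics, and the reverse-causality
model.  Tables land under results/.
"""

import json
from pathlib import Path

import pandas as pd

from actipat import reference as ref
from actipat import series as ser
from actipat import stats as st
from actipat.pipeline import ingest_stage

ROOT = Path(__file__).resolve().parents[1] / "results"


def reference_tables() -> None:
    print("reference cohort cross-tabs (stable vs shifting):")
    rows = []
    for key, spec in ref.GROUP_TABLES.items():
        res = st.categorical_test(spec["counts"])
        rows.append({"variable": key, "p": res.p_value, "method": res.method})
        print(f"  {key:13s} p = {res.p_value:.4f} ({res.method}); printed {ref.PRINTED_P[key]}")
    for seg in ("weekday", "weekend"):
        s = ref.EE_SUMMARY[seg]
        res = st.t_test_from_stats(*s["stable"], *s["shifting"])
        rows.append({"variable": f"daily_ee_{seg}", "p": res.p_value, "method": res.method})
        print(f"  daily EE {seg}: pooled t p = {res.p_value:.5f}")
    pd.DataFrame(rows).to_csv(ROOT / "reference_tests.csv", index=False)


def synthetic_cohort_stats() -> None:
    days, attrs, _ = ingest_stage(ROOT / "cohort")
    pat = pd.read_csv(ROOT / "patterns.csv", dtype={"participant_id": str})
    data = attrs.merge(pat[["participant_id", "group"]], on="participant_id")
    data = data[data["group"].notna()]
    ee = ser.daily_ee_table(days)

    comparison = st.group_comparison_table(data, ee)
    comparison.to_csv(ROOT / "group_comparison.csv", index=False)
    print("\nsynthetic cohort group comparison:")
    print(comparison[["variable", "level", "p", "method"]].to_string(index=False))

    fit = st.pattern_association_model(data)
    fit.table().to_csv(ROOT / "odds_ratios.csv", index=False)
    print("\nassociation model (outcome: shifting pattern):")
    print(fit.table().to_string(index=False))
    diag = st.diagnostics(fit)
    (ROOT / "diagnostics.json").write_text(
        json.dumps({k: v for k, v in diag.items() if k != "roc"}, indent=2)
    )
    pd.DataFrame(diag["roc"]).to_csv(ROOT / "roc_points.csv", index=False)
    print(
        f"diagnostics: pseudo-R2={diag['pseudo_r2']:.3f}, accuracy={diag['accuracy']:.2f}, "
        f"HL p={diag['hosmer_lemeshow_p']:.3f}, AUC={diag['auc']:.3f}"
    )

    rev = st.reverse_model(data)
    rev.table().to_csv(ROOT / "reverse_odds_ratios.csv", index=False)
    p = rev.table().set_index("term").loc["shifting", "p"]
    print(f"\nreverse model (outcome: >1 risk factors): shifting p = {p:.3f}")


def main() -> None:
    reference_tables()
    synthetic_cohort_stats()


if __name__ == "__main__":
    main()
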