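"""The repeated-measures choice analysis on the simulated trial tables.

Runs the full pipeline in the order it is meant to be used: collinearity
screen of the measured confounders, PCA of the ambient-lux pair, the
side-bias control model, then for each response (avoidance probability,
latency, head and body movement rates) the four-step two-way-interaction
ladder, estimated marginal means by color, marginal/conditional R², and
repeatability with a parametric-bootstrap CI.

Reads results/trials.csv + results/side_bias_trials.csv (running
02_simulate_trials.py first if they are absent) and writes
results/choice_analysis.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import chromachoice as cc
from chromachoice.choice import (
    ambient_pca,
    attach_pca1,
    collinearity_screen,
    estimated_marginal_means,
    movement_rate,
    r2_mixed,
    repeatability,
    side_bias_test,
    stepwise_interaction_ladder,
)
from chromachoice.glmm import term_tests

RESULTS = Path(__file__).resolve().parent.parent / "results"

RESPONSES = {
    "avoidance": ("choice_avoid", "binomial"),
    "latency": ("latency_s", "gaussian"),
    "head_rate": ("head_rate", "gaussian"),
    "body_rate": ("body_rate", "gaussian"),
}


def main(seed: int = 1, n_boot: int = 500) -> dict:
    RESULTS.mkdir(exist_ok=True)
    trials_path = RESULTS / "trials.csv"
    if not trials_path.exists():
        trials = cc.synth_choice_dataset(cc.ChoiceSimParams(seed=seed))
        trials.to_csv(trials_path, index=False)
        cc.synth_side_bias_dataset(seed=seed).to_csv(
            RESULTS / "side_bias_trials.csv", index=False
        )
    df = pd.read_csv(trials_path)
    cc.validate_choice_table(df)
    df["head_rate"] = [movement_rate(c, d) for c, d in zip(df["head_events"], df["visible_s"])]
    df["body_rate"] = [movement_rate(c, d) for c, d in zip(df["body_events"], df["visible_s"])]

    screen = collinearity_screen(df, ["lux_on", "lux_off", "temp_C"])
    pca = ambient_pca(df)
    df = attach_pca1(df)

    side = pd.read_csv(RESULTS / "side_bias_trials.csv")
    bias = side_bias_test(side)

    report = {
        "collinearity": screen.to_dict(orient="records"),
        "ambient_pca": {
            "eigenvalues": pca.eigenvalues.tolist(),
            "pct_variance_pc1": float(100 * pca.proportion_variance[0]),
            "loadings_pc1": pca.loadings[:, 0].tolist(),
        },
        "side_bias": {k: v for k, v in bias.items() if k != "fit"},
        "responses": {},
    }
    print(f"ambient lux r = {screen.iloc[0]['r']:.2f}; "
          f"PCA1 eigenvalue {pca.eigenvalues[0]:.2f} "
          f"({100 * pca.proportion_variance[0]:.1f}% of variance)")
    print(f"side bias: intercept {bias['intercept']:.2f} ± {bias['se']:.2f} "
          f"(z = {bias['z']:.2f}, P = {bias['p_value']:.3f})")

    for label, (col, family) in RESPONSES.items():
        fit, ladder = stepwise_interaction_ladder(df, col, family=family)
        marg, cond = r2_mixed(fit)
        rep = repeatability(fit, n_boot=n_boot, seed=seed)
        emm = estimated_marginal_means(fit, "color")
        report["responses"][label] = {
            "final_formula": ladder.final_formula,
            "kept_interactions": ladder.kept_interactions,
            "ladder": ladder.steps,
            "final_terms": term_tests(fit).to_dict(orient="records"),
            "emmeans_color": emm.to_dict(orient="records"),
            "r2_marginal_pct": marg,
            "r2_conditional_pct": cond,
            "repeatability_pct": rep.value,
            "repeatability_ci_pct": [rep.ci_low, rep.ci_high],
            "repeatability_category": rep.category,
            "singular_fit": fit.singular,
        }
        kept = ", ".join(ladder.kept_interactions) or "none"
        print(f"{label}: kept interactions [{kept}]; marginal R2 {marg:.1f}%, "
              f"conditional {cond:.1f}%; repeatability {rep.value:.1f}% "
              f"({rep.category}, CI {rep.ci_low:.1f}-{rep.ci_high:.1f})")

    def _jsonable(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(type(o))

    (RESULTS / "choice_analysis.json").write_text(
        json.dumps(report, indent=2, default=_jsonable)
    )
    return report


if __name__ == "__main__":
    import warnings

    warnings.filterwarnings("ignore", message=".*singular fit.*")
    main()
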