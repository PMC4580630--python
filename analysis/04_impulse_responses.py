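"""Impact multipliers and Monte Carlo impulse responses for one execution.

Refits the execution transfer-function model on the synthetic panel,
computes the long-run impact multiplier, and simulates the 12-month
impulse response 5000 times with both pointwise 68% percentile bands and
likelihood-shape bands.  The question the bands answer: once parameter
and residual-variance uncertainty are carried through, can the response
be distinguished from zero?
"""

from pathlib import Path

from txdeter import (
    MODEL_PRESETS,
    fit,
    impact_multiplier,
    load_panel,
    mc_irf,
    modal_irf,
    shape_bands,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240904


def main() -> None:
    panel = load_panel(OUT / "panel.csv")
    f = fit(panel["homicides"], MODEL_PRESETS["tf1"], exog=panel, strict=False)

    mult = impact_multiplier(f, "executions")
    modal = modal_irf(f, "executions", horizon=12)
    print(f"impact multiplier (long-run homicides per execution): {mult:.2f}")
    print(f"12-month cumulative modal response: {modal.cumulative[-1]:.2f}")

    resp = mc_irf(f, "executions", horizon=12, draws=5000, coverage=0.68, seed=SEED)
    resp.to_frame().to_csv(OUT / "irf_executions.csv", index=False)
    print(f"pointwise 68% band covers zero at every horizon: {resp.covers_zero()}")
    print(f"non-stationary parameter draws rejected: {resp.n_rejected}")

    shaped = shape_bands(resp)
    shaped.to_frame().to_csv(OUT / "irf_executions_shape.csv", index=False)
    width_pw = float((resp.upper - resp.lower).mean())
    width_sh = float((shaped.upper - shaped.lower).mean())
    print(f"mean band width, pointwise vs shape: {width_pw:.1f} vs {width_sh:.1f}")
    print(f"shape band covers zero at every horizon: {shaped.covers_zero()}")

    params_only = mc_irf(f, "executions", horizon=12, draws=5000, coverage=0.68,
                         seed=SEED, include_residual_uncertainty=False)
    ratio = float((resp.upper - resp.lower).mean()
                  / (params_only.upper - params_only.lower).mean())
    print(f"band-width inflation from residual-variance uncertainty: x{ratio:.0f}")


if __name__ == "__main__":
    main()
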