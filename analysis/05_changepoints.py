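"""Structural-break robustness check on the homicide series.

Fits the Bai-Perron multiple-break models to the synthetic panel: the
changing-means model, the autoregressive dynamics model (homicide lags 1
and 12), and the covariate model (adding the year-over-year percentage
change in prisoners and current/lagged executions), selecting the number
of breaks 0..5 by BIC.  Also verifies break-location recovery on a panel
with an injected 5-sigma mean shift.
"""

from pathlib import Path

import numpy as np

from txdeter import (
    BREAK_PRESETS,
    BreakSpec,
    SyntheticConfig,
    build_break_design,
    generate_panel,
    inject_break,
    load_panel,
    select_breaks,
)
from txdeter.changepoint import default_min_segment

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240909


def main() -> None:
    panel = load_panel(OUT / "panel.csv")
    for name, regs in BREAK_PRESETS.items():
        y, Z = build_break_design(panel, regs)
        h = default_min_segment(len(y), len(regs))
        bf = select_breaks(y, Z, BreakSpec(regs, h, 5))
        bf.regime_table().to_csv(OUT / f"{name}.csv")
        dates = bf.break_months()
        print(f"{name}: m={bf.m} break(s) at {dates or '(none)'}; "
              f"R2={bf.r2:.3f}, sigma2={bf.sigma2:.1f}")
        print(f"  BIC trace: { {m: round(b, 1) for m, b in bf.bic_trace.items()} }")

    # constructed truth: stationary, mildly autocorrelated panel with a
    # single injected mean shift (no trend or covariate confounds)
    clean = SyntheticConfig(seed=SEED, trend=0.0, beta_exec=(0.0, 0.0),
                            beta_prisoners=0.0, beta_unemp=0.0,
                            ar=(0.3, 0.1, 0.1), seasonal_ar=0.0, seasonal_ma=0.0)
    base = generate_panel(clean)
    shifted = inject_break(base, month=70,
                           deltas={"mean_level": 5 * clean.innovation_sd})
    y = shifted.homicides
    bf = select_breaks(y, np.ones((len(y), 1)),
                       BreakSpec(("intercept",), default_min_segment(len(y), 1), 5))
    print(f"\ninjected 5-sigma mean shift at month 70 (0-based): "
          f"recovered m={bf.m}, regime-1 end index={bf.breaks[0] if bf.breaks else None} "
          f"(truth 69)")


if __name__ == "__main__":
    main()
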