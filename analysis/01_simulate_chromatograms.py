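"""Simulate the study's chromatograms: the mixed standard at each detection
wavelength, one sample batch, and a negative control lacking the
Sophora-derived alkaloids (matrine, oxymatrine).

Writes one CSV per trace under results/chromatograms/ and a four-panel
overview figure, and prints where each analyte's peak sits.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from qams_hplc.chromsim import simulate_chromatogram, simulate_negative_control
from qams_hplc.study import default_study, simulation_config


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/chromatograms"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    study = default_study(seed=args.seed)
    mixed = study.mixed_standard_concentrations()
    sample = study.batch_concentrations(next(iter(study.batches)))

    fig, axes = plt.subplots(len(study.channels), 1, figsize=(9, 10), sharex=True)
    for ax, channel in zip(axes, study.channels):
        std_sim = simulation_config(study, mixed, 5.0, args.seed)
        standard = simulate_chromatogram(std_sim, channel)
        standard.sample_id = f"mixed-standard-{int(channel)}nm"
        standard.to_csv(args.out / f"standard_{int(channel)}nm.csv")

        sample_sim = simulation_config(study, sample, 5.0, args.seed + 1)
        test = simulate_chromatogram(sample_sim, channel)
        test.sample_id = f"sample-{int(channel)}nm"
        test.to_csv(args.out / f"sample_{int(channel)}nm.csv")

        control = simulate_negative_control(sample_sim, {"matrine", "oxymatrine"}, channel)
        control.to_csv(args.out / f"negative_control_{int(channel)}nm.csv")

        ax.plot(standard.times, standard.signal, lw=0.6, label="mixed standard")
        ax.plot(control.times, control.signal, lw=0.6, alpha=0.7, label="negative control")
        ax.set_ylabel(f"{int(channel)} nm")
        ax.legend(loc="upper right", fontsize=7)
        names = [a.name for a in study.analytes if a.wavelength == channel]
        print(f"{int(channel)} nm: {', '.join(names)} at "
              + ", ".join(f"{study.analyte(n).retention_time:.1f} min" for n in names))
    axes[-1].set_xlabel("time (min)")
    fig.tight_layout()
    fig.savefig(args.out / "overview.png", dpi=120)
    print(f"wrote {3 * len(study.channels)} traces and overview.png to {args.out}")


if __name__ == "__main__":
    main()
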