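"""Generate the synthetic DOE study that stands in for the expansion data.

Writes a 26-run D-optimal design over the four process parameters
(activations, seed-train days, seeding density, IL-2), end-of-culture marker
percentages, and per-run daily culture/metabolite time series, plus the
generating ground truth for reference.
"""

from common import config

from cartdoe.io import simulate_study_files


def main() -> None:
    cfg = config()
    simulate_study_files(cfg)
    print(f"synthetic study (seed {cfg.seed}) written under {cfg.data_dir}:")
    for name in ("responses.csv", "counts.csv", "metabolites.csv",
                 "ground_truth.json"):
        print(f"  {cfg.data_dir / name}")


if __name__ == "__main__":
    main()
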