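"""Identify optimised and sub-optimised process settings by desirability.

Maximises growth (cumulative population doublings) while minimising the
PD1+LAG3+ exhaustion-marker percentage, with equal weights, over the full
lattice of tested factor levels.
"""

from common import config

from cartdoe.design import default_space
from cartdoe.io import _write_csv, assemble_response_table, fit_stage, write_json
from cartdoe.optimise import OptimisationSpec, find_optimum


def main() -> None:
    cfg = config()
    space = default_space()
    table = assemble_response_table(cfg, space)
    models, _ = fit_stage(cfg, space, table)
    spec = OptimisationSpec(goals={r: g for r, g in cfg.goals.items()
                                   if r in models})
    result = find_optimum(models, space, spec)

    tag = f"config_hash={cfg.config_hash()}"
    _write_csv(cfg.out_dir / "desirability_ranking.csv", result.table, tag)
    write_json(cfg.out_dir / "optimum.json", result.to_dict())

    def fmt(settings):
        return (f"activations={settings['activations']:.0f}, "
                f"seed train={settings['seed_train_days']:.0f} d, "
                f"density={settings['seeding_density']:.3g}, "
                f"IL-2={settings['il2_iu_per_ml']:.0f} IU/mL")

    print("optimised settings:     " + fmt(result.best))
    print("sub-optimised settings: " + fmt(result.worst))
    for resp, value in result.best_predictions.items():
        worst = result.worst_predictions[resp]
        print(f"  predicted {resp}: {value:.2f} (optimised) vs {worst:.2f} (worst)")
    if result.inactive_factors:
        print(f"inactive factors (all levels tie, lowest reported): "
              f"{', '.join(result.inactive_factors)}")


if __name__ == "__main__":
    main()
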