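"""Fit the DOE regression model for each response and validate it.

Backward-eliminates the full interaction model at alpha = 0.05 (respecting
hierarchy), reports R2, leave-one-out Q2 and the overall model p-value, and
writes plot-ready coefficient, interaction and contour tables for the growth
and exhaustion responses.
"""

from common import config

from cartdoe.design import default_space
from cartdoe.io import _write_csv, assemble_response_table, fit_stage, write_json
from cartdoe.mlr import coefficient_table, contour_grid, interaction_view


def main() -> None:
    cfg = config()
    space = default_space()
    table = assemble_response_table(cfg, space)
    models, failures = fit_stage(cfg, space, table)
    tag = f"config_hash={cfg.config_hash()}"

    _write_csv(cfg.out_dir / "response_table.csv", table, tag)
    write_json(cfg.out_dir / "models.json",
               {r: m.to_dict() for r, m in models.items()})

    print(f"{'response':<14}{'R2':>8}{'Q2':>8}{'gap':>8}{'model p':>12}  terms")
    for resp, m in models.items():
        print(f"{resp:<14}{m.r2:>8.3f}{m.q2:>8.3f}{m.r2 - m.q2:>8.3f}"
              f"{m.model_p:>12.2e}  {', '.join(m.term_labels[1:])}")
        flag = "" if m.validity["r2_q2_gap_ok"] else "  <-- over-optimistic (gap > 0.2)"
        if flag:
            print(flag)

    for resp in ("cpd", "pd1lag3_pct"):
        if resp not in models:
            continue
        m = models[resp]
        _write_csv(cfg.out_dir / f"coefficients_{resp}.csv",
                   coefficient_table(m), tag)
        if {"activations", "seed_train_days"} <= m.factors_in_model():
            _write_csv(cfg.out_dir / f"interaction_{resp}.csv",
                       interaction_view(m, space, "seed_train_days",
                                        "activations"), tag)
        two = [f for f in ("seed_train_days", "seeding_density")
               if f in m.factors_in_model()]
        if len(two) == 2:
            _write_csv(cfg.out_dir / f"contour_{resp}.csv",
                       contour_grid(m, space, *two,
                                    reference={"activations": 1,
                                               "il2_iu_per_ml": 30}), tag)
    if failures:
        raise SystemExit("; ".join(failures))


if __name__ == "__main__":
    main()
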