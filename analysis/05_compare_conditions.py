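"""Compare single- vs double-activation runs on every response.

Brown-Forsythe variance pre-check drives the choice of pooled vs Welch
t-test; p-values carry the conventional star notation.
"""

from common import config

from cartdoe.design import default_space
from cartdoe.groupstats import comparison_table
from cartdoe.io import _write_csv, assemble_response_table


def main() -> None:
    cfg = config()
    table = assemble_response_table(cfg, default_space())
    responses = [r for r in cfg.responses if r in table.columns]
    comparisons = comparison_table(table, "activations", responses)
    _write_csv(cfg.out_dir / "group_comparisons.csv", comparisons,
               f"config_hash={cfg.config_hash()}")
    cols = ["response", "mean_a", "mean_b", "test", "p_value", "stars"]
    print(comparisons[cols].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
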