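"""Fit the linear mixed-effects models of the entry-segment kinematics.

Two log-linear mixed models relate the expansion-acceleration rdot_e and
the mean approach acceleration Ae to starting distance y0, required step
dre, set-point r*, light condition and landing type, with random intercepts
for day, approach number and landing side.  Prints coefficient tables,
Bonferroni-adjusted contrasts and model-predicted means at reference
covariate settings.
"""

import json
from pathlib import Path

import click
import numpy as np
import pandas as pd

from beeland.stats import fit_lmm, posthoc_contrasts, predict_emm


@click.command()
@click.option("--entries", default="results/entries.csv", show_default=True)
@click.option("--out-dir", default="results", show_default=True, type=click.Path())
def main(entries, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tab = pd.read_csv(entries)
    pos = tab[(tab.delta_re_per_s > 0) & (tab.rdot_per_s2 > 0)]

    results = {}
    for response, sel in [("rdot_per_s2", pos),
                          ("Ae_mean_ms2", pos[pos.Ae_mean_ms2 > 0])]:
        if len(sel) < 30:
            click.echo(f"{response}: only {len(sel)} usable entries, skipped")
            continue
        res = fit_lmm(sel, response)
        click.echo(f"\n== {response} model (n = {res.n_obs}) ==")
        click.echo(res.fixed_effects.round(3).to_string())
        click.echo("random SDs: " + ", ".join(
            f"{k} {v:.3f}" for k, v in res.random_sd.items()))
        con = posthoc_contrasts(res)
        click.echo(con.round(4).to_string(index=False))
        results[response] = {
            "fixed_effects": res.fixed_effects.to_dict(orient="index"),
            "random_sd": res.random_sd,
            "n_obs": res.n_obs,
            "contrasts": con.to_dict(orient="records"),
        }
        if response == "rdot_per_s2":
            med = dict(delta_re=float(pos.delta_re_per_s.median()),
                       r_star=float(pos.r_star_per_s.median()))
            emm = predict_emm(res, [dict(y0=0.1, light="sunrise", **med),
                                    dict(y0=0.3, light="sunrise", **med)])
            click.echo("predicted rdot at y0 = 0.1 / 0.3 m (sunrise, medians):")
            click.echo(emm[["y0", "mean", "ci_low", "ci_high"]].round(2).to_string(index=False))
            results[response]["emm_y0"] = emm.to_dict(orient="records")

    (out / "lmm_results.json").write_text(json.dumps(results, indent=2, default=float))


if __name__ == "__main__":
    main()
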