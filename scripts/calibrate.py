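#!/usr/bin/env python
"""Calibration harness for the default KRAS-mutant parameter set.

The kinetic constants of the cascade are not identifiable from any published
table; they were reconstructed from the classic distributive-MAPK model
lineage and then adjusted until the behavioural constraint suite below is
satisfied.  This script evaluates that suite for a parameter file (default:
the shipped ``params_default.yaml``) and prints a pass/fail report, so the
frozen defaults remain auditable and re-derivable.

Constraint suite (all on the RAS-coupled network with both inhibitors):
  C1  vehicle steady-state free ppERK >= 20% of total ERK
      (chronically elevated pathway activity);
  C2  MEKi at its output-EC50: output nadir reached within 6 h and rebound
      index >= 0.5 at 72 h (feedback-driven pathway reactivation);
  C3  the same dose with DUSP and SPRY feedback disabled: rebound < 0.05
      (reactivation requires the transcriptional feedbacks);
  C4  half-dose MEKi+ERKi combination: 0-72 h output AUC strictly below each
      full-dose single agent (fractional-dose combination superiority);
  C5  6-h active-CRAF fold-changes ordered combo > MEKi >= ERKi > 1 with the
      MEKi fold in the 2-4 band;
  C6  RAS-coupled vs RAF-decoupled Loewe contrast on the zero-anchored
      9x9 matrix: coupled score > 10x |decoupled score| and the decoupled
      score inside the sham additivity band.

Usage:
    python scripts/calibrate.py [--params FILE] [--skip-contrast]
"""

import argparse
import sys
import warnings

import numpy as np

from mapkdual import (
    FeedbackConfig, MapkCascade, ModelParameters, compare_fractional_combo,
    craf_activity, build_network, default_inhibitors, load_default_parameters,
    rebound_index, simulate,
)
from mapkdual.network import DrugTarget, output_ec50
from mapkdual.doseresponse import ViabilityLink, zero_anchored_dose_grid
from mapkdual.reactivation import ras_vs_braf_contrast


def check(label, ok, detail):
    print(f"  [{'PASS' if ok else 'FAIL'}] {label}: {detail}")
    return ok


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--params", default=None, help="parameter YAML to evaluate")
    ap.add_argument("--skip-contrast", action="store_true",
                    help="skip the (slower) coupled-vs-decoupled contrast")
    args = ap.parse_args(argv)

    params = (ModelParameters.from_yaml(args.params) if args.params
              else load_default_parameters())
    inhibitors = default_inhibitors()
    net = build_network(params, FeedbackConfig(), inhibitors)
    veh = net.vehicle_output
    erk_tot = params.erk_total
    results = []

    print("Behavioural calibration report")
    print("=" * 60)
    results.append(check(
        "C1 vehicle output", veh / erk_tot >= 0.20,
        f"free ppERK {veh:.1f} nM = {veh / erk_tot:.1%} of ERK total"))

    ec_m = output_ec50(net, DrugTarget.MEK)
    ec_e = output_ec50(net, DrugTarget.ERK)
    print(f"  reference output-EC50s: MEKi {ec_m:.3g} nM, ERKi {ec_e:.3g} nM")

    traj_m = simulate(net, ec_m, 0.0)
    nadir_t = float(traj_m.times[np.argmin(traj_m.pathway_output)])
    reb = rebound_index(traj_m)
    results.append(check(
        "C2 reactivation", nadir_t <= 6.0 and reb.defined and reb.value >= 0.5,
        f"nadir at {nadir_t:.1f} h, rebound index {reb.value:.3f}"))

    net_off = build_network(
        params, FeedbackConfig(fb_dusp=False, fb_spry=False), inhibitors)
    reb_off = rebound_index(simulate(net_off, ec_m, 0.0))
    results.append(check(
        "C3 feedback ablation", (not reb_off.defined) or reb_off.value < 0.05,
        f"rebound {reb_off.value:.4f} with DUSP/SPRY feedback off"))

    comp = compare_fractional_combo(net, ec_m, ec_e)
    aucs = {k: comp.auc(k) / (veh * 72.0) for k in ("mek", "erk", "combo")}
    results.append(check(
        "C4 fractional combo", comp.combo_dominates,
        "output AUC/vehicle: " + ", ".join(f"{k} {v:.3f}" for k, v in aucs.items())))

    folds = {}
    for label, dm, de in (("mek", ec_m, 0.0), ("erk", 0.0, ec_e),
                          ("combo", ec_m / 2, ec_e / 2)):
        traj = simulate(net, dm, de, t_end=6.0)
        folds[label] = float(craf_activity(traj)[-1])
    ok5 = (folds["combo"] > folds["mek"] >= folds["erk"] > 1.0
           and 2.0 <= folds["mek"] <= 4.0)
    results.append(check(
        "C5 CRAF induction", ok5,
        "6-h folds: " + ", ".join(f"{k} {v:.2f}" for k, v in folds.items())))

    if not args.skip_contrast:
        link = ViabilityLink()
        doses = zero_anchored_dose_grid()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ras_vs_braf_contrast(params, doses, doses, link, inhibitors)
        ok6 = (res.score_coupled > 10.0 * abs(res.score_decoupled)
               and res.decoupled_additive)
        results.append(check(
            "C6 coupled-vs-decoupled", ok6,
            f"Loewe scores: coupled {res.score_coupled:.3f}, decoupled "
            f"{res.score_decoupled:+.4f}, sham band +/-{res.sham_band:.3f}"))

    print("=" * 60)
    n_pass = sum(results)
    print(f"{n_pass}/{len(results)} constraints satisfied")
    return 0 if n_pass == len(results) else 1


if __name__ == "__main__":
    sys.exit(main())
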