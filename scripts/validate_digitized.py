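#!/usr/bin/env python
"""Refit the model to externally supplied digitized protocol curves.

The reference parameter table in ``fluidshift.protocols`` was obtained by
fitting protocol-average fractional-blood-volume curves that were digitized
from published figures.  Those curves are third-party data and are not
distributed with this package.  If you digitize them yourself (or have your
own hemodilution-derived traces), this script refits each protocol and
compares the estimates with the stored reference values.

Usage:
    python scripts/validate_digitized.py --data-dir DIR [--out report.json]

DIR must contain one trace CSV per protocol you wish to validate, named
``<protocol>.csv`` with columns ``time_min, vb_frac`` (see the package I/O
contract), where <protocol> is one of:
    ringers_acetate_0ml  ringers_acetate_450ml  ringers_acetate_900ml
    saline  ringers_lactate  albumin  autologous_plasma

Optionally provide ``<protocol>.weight`` (a single number, kg) and
``<protocol>.urine`` (total urine volume, ml) alongside each CSV; defaults
are 75 kg and no urine.  Because the per-protocol subject weights and urine
totals of the source studies are not recoverable, exact agreement with the
reference table is not expected — order-of-magnitude and trend agreement is
the realistic goal.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import fluidshift as fs
from fluidshift.io import read_trace


def validate_protocol(name: str, data_dir: Path) -> dict | None:
    csv = data_dir / f"{name}.csv"
    if not csv.exists():
        return None
    trace = read_trace(csv)
    spec = fs.PROTOCOLS[name]
    weight_file = data_dir / f"{name}.weight"
    urine_file = data_dir / f"{name}.urine"
    weight = float(weight_file.read_text()) if weight_file.exists() else None
    if urine_file.exists():
        spec = dataclasses.replace(spec,
                                   total_urine_ml=float(urine_file.read_text()))
    schedule = fs.schedule_from_protocol(spec, weight_kg=weight)
    fit = fs.fit_model(trace, schedule)
    ref = fs.REFERENCE_FITS[name]
    return {
        "n_samples": len(trace),
        "fitted": {"alpha": fit.params_star.alpha,
                   "K_per_min": fit.params_star.K,
                   "V_B0_l": fit.params_star.V_B0 / 1000.0},
        "reference": {"alpha": ref.alpha, "K_per_min": ref.K,
                      "V_B0_l": ref.V_B0_l},
        "rmsne_pct": fit.rmsne,
        "reference_rmse_pct": ref.rmse_pct,
    }


def main():
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--data-dir", type=Path, required=True,
                    help="directory with <protocol>.csv trace files")
    ap.add_argument("--out", type=Path, default=None,
                    help="optional JSON report path")
    args = ap.parse_args()

    report = {}
    for name in fs.PROTOCOLS:
        result = validate_protocol(name, args.data_dir)
        if result is None:
            print(f"[skip] {name}: no {name}.csv in {args.data_dir}")
            continue
        report[name] = result
        f, r = result["fitted"], result["reference"]
        print(f"[fit]  {name}: alpha={f['alpha']:.3g} (ref {r['alpha']}), "
              f"K={f['K_per_min']:.3g}/min (ref {r['K_per_min']}), "
              f"V_B0={f['V_B0_l']:.3g} l (ref {r['V_B0_l']}), "
              f"RMSNE={result['rmsne_pct']:.3g}%")
    if not report:
        raise SystemExit("no protocol traces found; nothing validated")
    if args.out:
        args.out.write_text(json.dumps(report, indent=2) + "\n")
        print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
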