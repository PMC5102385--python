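"""Rotational correlation times from ¹⁵N relaxation.

Round-trips the rigid-rotor forward model at the two reported correlation
times (di-domain 14.1 ns, homodimer 18.2 ns), then estimates τc from the
noisy simulated table (2% noise, 20% flexible loops) with the NOE > 0.75
rigidity filter.  Writes results/relaxation/tc.json.
"""

import json
from pathlib import Path

import pandas as pd

from gagfold.relaxation import (
    RelaxRecord,
    SpinParams,
    ensemble_tc,
    estimate_tc,
    predict_relaxation,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "relaxation"
SP = SpinParams(700.0)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    report = {}

    for label, tau_ns in (("didomain", 14.1), ("homodimer", 18.2)):
        t1, t2, noe = predict_relaxation(tau_ns * 1e-9, SP)
        est = estimate_tc(RelaxRecord("r", t1, t2, noe), SP) * 1e9
        report[label] = {"tau_c_in_ns": tau_ns, "T1_s": t1, "T2_s": t2,
                         "NOE": noe, "tau_c_out_ns": est}
        print(f"{label}: tau_c {tau_ns} ns -> T1 {t1:.3f} s, T2 {t2 * 1e3:.1f} ms, "
              f"inverts to {est:.2f} ns")

    table = ROOT / "inputs" / "relaxation.tsv"
    if table.exists():
        df = pd.read_csv(table, sep="\t")
        records = [RelaxRecord(str(r.residue), r.T1_s, r.T2_s, r.NOE)
                   for r in df.itertuples()]
        est = ensemble_tc(records, SP, noe_cutoff=0.75)
        report["simulated_table"] = {
            "tau_c_ns": est.tau_c, "n_used": est.n_used,
            "n_records": len(records), "cutoff": est.cutoff,
        }
        print(f"simulated table: tau_c = {est.tau_c:.2f} ns from "
              f"{est.n_used}/{len(records)} rigid residues (truth 14.1)")

    (OUT / "tc.json").write_text(json.dumps(report, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
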