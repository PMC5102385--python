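"""Generate the synthetic inputs used by the downstream analyses.

Writes a domain quartet (CA-only PDB), multi-speed sedimentation-equilibrium
profiles (TSV) and a per-residue relaxation table (TSV) under
results/inputs/, all from one master seed.
"""

import json
from pathlib import Path

import pandas as pd

from gagfold.hydrodynamics import BuoyancyParams
from gagfold.relaxation import SpinParams
from gagfold.structures import write_ca_pdb
from gagfold.synthetic_data import (
    generate_relaxation_dataset,
    generate_se_dataset,
    make_homology_quartet,
)

SEED = 20260926
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    quartet = make_homology_quartet(SEED)
    for name in ("spuma_n", "spuma_c", "ortho_n", "ortho_c"):
        write_ca_pdb(getattr(quartet, name), OUT / f"{name}.pdb")
    print(f"quartet: 4 CA-only PDBs "
          f"({len(quartet.spuma_n)} and {len(quartet.spuma_c)} residues)")

    params = BuoyancyParams(11894.0, 0.7312, 1.005, 293.0)
    profiles = generate_se_dataset(
        params, kd=0.9e-6, loadings=(2e-5, 5e-5, 1e-4),
        speeds=(15000, 20000, 25000), noise_sd_frac=0.005, seed=SEED,
    )
    rows = [
        {"radius_cm": r, "signal": s, "speed_rpm": pr.speed_rpm,
         "sample_id": pr.sample_id}
        for pr in profiles for r, s in zip(pr.radii, pr.signal)
    ]
    pd.DataFrame(rows).to_csv(OUT / "se_profiles.tsv", sep="\t", index=False)
    print(f"sedimentation equilibrium: {len(profiles)} profiles "
          f"(3 loadings x 3 speeds, K_D 0.9 uM, 0.5% noise)")

    records = generate_relaxation_dataset(
        14.1e-9, SpinParams(700.0), n_residues=50, noise_frac=0.02,
        loop_fraction=0.2, seed=SEED,
    )
    pd.DataFrame(
        [{"residue": r.residue, "T1_s": r.T1, "T2_s": r.T2, "NOE": r.noe}
         for r in records]
    ).to_csv(OUT / "relaxation.tsv", sep="\t", index=False)
    print("relaxation: 50 residues at tau_c 14.1 ns (20% flexible loops)")

    (OUT / "manifest.json").write_text(json.dumps({"seed": SEED}, indent=2))


if __name__ == "__main__":
    main()
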