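"""Run the whole pipeline from a config dict and inspect the output files.

Equivalent to `rohscan run --config pipeline.yaml`: simulate -> write VCF ->
QC -> ROH calling -> inbreeding tables -> islands -> manifest.
"""

import json
import tempfile
from pathlib import Path

from rohscan import run_pipeline

out_dir = run_pipeline(
    {
        "seed": 5,
        "simulate": {
            "n_individuals": 15,
            "n_chromosomes": 2,
            "chrom_length_bp": 20_000_000,
            "n_snps_per_chrom": 10_000,
            "tract_spec": [
                [0, "1", 4_000_001, 7_000_000],
                [1, "2", 8_000_001, 12_000_000],
            ],
            "het_error_rate": 0.0,
            "missing_rate": 0.0,
        },
        "qc": {"max_missing_rate": 0.1, "min_maf": 0.05},
    },
    tempfile.mkdtemp(prefix="rohscan_demo_"),
)

out = Path(out_dir)
print(f"pipeline outputs in {out}:\n")
for f in sorted(out.iterdir()):
    print(f"  {f.name}")

manifest = json.loads((out / "manifest.json").read_text())
print(f"\nmanifest: {manifest['n_segments']} ROH segments, "
      f"{manifest['n_islands']} islands, L_aut = {manifest['l_aut']:,} bp, "
      f"QC kept {manifest['qc']['n_kept']} of {manifest['qc']['n_input']} SNPs")

print("\nroh_segments.tsv:")
print((out / "roh_segments.tsv").read_text())
print(
    "Re-running with the same config and seed reproduces every file "
    "byte-for-byte; the manifest records the parameters, the input VCF "
    "checksum and the package version for provenance."
)
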