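"""24-nt phasiRNA promoter targeting and RdDM methylation comparison.

Consumes results/scenarios/rddm from 01_simulate.py: finds the planted
24-mer binding sites on the promoter, profiles CG/CHG/CHH methylation per
tissue from the bisulfite reads, computes target-gene expression in RPM,
and reports whether the pattern is RdDM-consistent (higher CHH
methylation and lower expression in the phasiRNA-expressing tissue).
"""

import json
from pathlib import Path

from phasloc.pipeline import run_rddm

ROOT = Path(__file__).resolve().parents[1]
SCENARIO = ROOT / "results" / "scenarios" / "rddm"
OUT = ROOT / "results" / "rddm"


def main() -> None:
    manifest = json.loads((SCENARIO / "manifest.json").read_text())
    config = {
        "base_dir": str(SCENARIO),
        "promoters": "promoters.fasta",
        "cdnas": "cdnas.fasta",
        "phasirnas": "phasirnas.tsv",
        "bisulfite": {
            t: f"bisulfite_{t}.tsv"
            for t in (manifest["expressing_tissue"], manifest["other_tissue"])
        },
        "rnaseq": {
            t: f"rnaseq_{t}.tsv"
            for t in (manifest["expressing_tissue"], manifest["other_tissue"])
        },
        "promoter_target_map": manifest["promoter_target_map"],
        "expressing_tissue": manifest["expressing_tissue"],
        "other_tissue": manifest["other_tissue"],
    }
    result = run_rddm(config, OUT)
    hits = result["hits"]
    print(f"promoter hits found: {len(hits)} (planted: {len(manifest['planted_hits'])})")
    for h in hits:
        print(f"  {h.phasirna_name} -> {h.promoter_id}:{h.start}-{h.end} ({h.orientation})")
    for c in result["comparisons"]:
        print(
            f"{c.promoter_id}: CHH {c.chh_expressing:.0f} vs {c.chh_other:.0f} RPM, "
            f"expression {c.expression_expressing:.0f} vs {c.expression_other:.0f} RPM "
            f"-> {'consistent' if c.consistent else 'not consistent'} RdDM"
        )


if __name__ == "__main__":
    main()
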