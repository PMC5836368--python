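#!/usr/bin/env python
"""Observed-peptide terminus classification: trypsin vs chymotrypsin.

Simulates observed-peptide sets (full detection in the 8-25 aa window)
from tryptic and chymotryptic digests of the K/R-biased genome, writes
them as BED12, classifies every uniquely mapped peptide's termini
relative to splice sites (types 1-4), and reports the per-offset
boundary-distance histograms with z-tests.
"""

import json
from pathlib import Path

import pandas as pd

from splicepep import (
    JunctionIndex,
    boundary_distance_histogram,
    build_coding_transcripts,
    classify_peptides,
    enumerate_junctions,
    get_enzyme,
    read_gene_models,
    read_genome,
    type_ratio_summary,
    write_bed12,
)
from splicepep.simulate import simulate_observed_peptides

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim" / "kr_biased"
OUT = ROOT / "results" / "observed"
SEED = 104


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = read_genome(SIM / "genome.fa")
    models = read_gene_models(SIM / "annotation.genePred", genome=genome)
    cts = build_coding_transcripts(models, genome)
    jcts = enumerate_junctions(cts)
    index = JunctionIndex(jcts)
    window = lambda n: 1.0 if 8 <= n <= 25 else 0.0

    summaries = {}
    for name in ("trypsin", "chymotrypsin"):
        obs = simulate_observed_peptides(cts, get_enzyme(name), window, SEED)
        write_bed12(obs, OUT / f"observed_{name}.bed")
        calls = classify_peptides(obs, index)
        summary = type_ratio_summary(calls)
        summaries[name] = summary
        fr = summary["fractions"]
        print(f"{name}: {summary['n_peptides']} uniquely mapped peptides; "
              f"type 1-4 fractions "
              f"{fr[1]:.3f}/{fr[2]:.3f}/{fr[3]:.3f}/{fr[4]:.3f}; "
              f"summed {100*summary['summed_ratio']:.1f}%")
        hists = boundary_distance_histogram(obs, index)
        frames = []
        for cat, h in hists.items():
            df = h.to_frame()
            df.insert(0, "category", cat)
            frames.append(df)
        pd.concat(frames).to_csv(OUT / f"histograms_{name}.tsv",
                                 sep="\t", index=False)
        h0 = hists["starts_vs_acceptor"]
        print(f"   starts at splice site: {int(h0.counts[0])} "
              f"(z={h0.z[0]:.1f}, p={h0.p[0]:.2g})")

    ratio_t = summaries["trypsin"]["summed_ratio"]
    ratio_c = summaries["chymotrypsin"]["summed_ratio"]
    print(f"\ntrypsin produces {ratio_t / max(ratio_c, 1e-9):.0f}x the "
          f"boundary-coincident (type 1-4) peptide fraction of chymotrypsin")
    (OUT / "type_summaries.json").write_text(json.dumps(summaries, indent=2))
    print(f"wrote tables under {OUT}")


if __name__ == "__main__":
    main()
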