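"""Generate the full synthetic study bundle with planted ground truth.

Writes Sanger trace sets (sample + controls), plate-count tables, colony
amplicon reads and digest-lane tables under results/simulated/, each with
its truth file, so the downstream drivers (02-05) can measure how well the
estimators recover what was planted.
"""

import sys
from pathlib import Path

from sstrkit import synthgen

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # Trace sets: three biological replicates with symmetric 30% editing at
    # every panel position, realistic context multipliers and background noise.
    for rep in range(1, 4):
        spec = synthgen.SynthTraceSpec(signal_noise_cv=0.03, seed=SEED + rep)
        bundle = synthgen.gen_trace_set(spec)
        synthgen.write_trace_set(bundle, OUT / f"traces_rep{rep}")
    print(f"traces: 3 replicate sets, planted editing 0.30 at positions "
          f"{synthgen.DEFAULT_PANEL_POSITIONS}")

    counts, truth = synthgen.gen_assay_counts(synthgen.SynthAssaySpec(seed=SEED))
    counts.to_csv(OUT / "plate_counts.tsv", sep="\t", index=False)
    truth.to_tsv(OUT / "truth_assay.tsv")
    print(f"plate counts: {len(counts)} replicates across "
          f"{counts['genotype'].nunique()} ssODN designs")

    read_spec = synthgen.SynthReadSpec(n_reads=100, seed=SEED)
    reads, rtruth = synthgen.gen_colony_reads(read_spec)
    synthgen.write_fasta(reads, OUT / "colony_reads.fasta")
    rtruth.to_tsv(OUT / "truth_reads.tsv")
    print(f"colony reads: {len(reads)} with category mix "
          f"{read_spec.category_mix}")

    lanes, gtruth = synthgen.gen_gel_lanes(
        true_eff_5prime=0.80, true_eff_3prime=0.72,
        band_model=synthgen.BandModel(noise_cv=0.01), seed=SEED, replicates=3,
    )
    lanes.to_csv(OUT / "gel_lanes.tsv", sep="\t", index=False)
    gtruth.to_tsv(OUT / "truth_gel.tsv")
    print("gel lanes: planted digestion efficiencies 0.80 (5') / 0.72 (3')")
    print(f"all outputs under {OUT}")


if __name__ == "__main__":
    main()
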