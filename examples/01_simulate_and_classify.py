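"""Simulate isomiR reads with a known spectrum and recover it exactly.

Builds two synthetic hairpins, plants a five-isoform spectrum on one arm
(canonical, 3' deletion, uridylated tail, 5' deletion, mixed), generates
error-free reads, and runs trimming -> alignment -> classification. At zero
error rate the recovered table equals the planted truth read-for-read.
"""

from isomirseq import IsomiRSpectrumConfig, SpectrumEntry, simulate_reads
from isomirseq.isomir import build_isomir_table, isomir_frame
from isomirseq.pipeline import default_synthetic_references
from isomirseq.preprocess import align_sample, collapse_and_filter, trim_adapter

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

hairpins, arms = default_synthetic_references(seed=0)
spectrum = {
    "syn-miR-1-5p": [
        SpectrumEntry(0, 0, "", 0.55),    # canonical ("0|0")
        SpectrumEntry(0, -1, "", 0.20),   # 3' deletion ("0|-1")
        SpectrumEntry(0, 0, "T", 0.10),   # uridylated NTA
        SpectrumEntry(2, 0, "", 0.10),    # 5' deletion ("+2|0"), shifted seed
        SpectrumEntry(1, -2, "", 0.05),   # mixed ("+1|-2")
    ]
}
cfg = IsomiRSpectrumConfig(spectrum, reads_per_sample=5000,
                           sequencing_error_rate=0.0, rng_seed=1)
reads, truth = simulate_reads(cfg, hairpins, arms, samples=["demo"])

trimmed = [trim_adapter(seq, ADAPTER)[0] for seq, _ in reads["demo"]]
collapsed, ftally = collapse_and_filter(trimmed)
aligned, atally = align_sample(collapsed, hairpins, arms)
records = build_isomir_table({"demo": aligned}, hairpins, ["demo"])

print(f"reads in: {ftally.input}, kept: {ftally.kept}, "
      f"assigned to arms: {atally.assigned}")
print()
print(isomir_frame(records, ["demo"]).to_string())
print()
print("Each row is one distinct isoform: the label 's|e' gives the signed")
print("5'/3' terminal shifts vs the archetype, 'nta' the non-templated 3'")
print("tail. Counts match the planted spectrum (55/20/10/10/5%) exactly.")
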