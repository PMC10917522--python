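"""From peptide evidence to protein abundance: digestion, ppm and iBAQ.

ppm expresses each protein as parts per million of the total quantified
signal in a sample (so each sample's column sums to exactly 1,000,000);
iBAQ divides summed peptide intensity by the protein's theoretical peptide
count, approximating molar amounts.
"""

import brewtrack as bt

config = bt.SimulationConfig(n_proteins=50, seed=2)
records, truth = bt.generate_proteome(config)
evidence, metadata = bt.generate_evidence(config, records, truth)
proteome = bt.proteome_dict(records)

# in-silico tryptic digestion of one protein (cleave after K/R, not before P)
pid = records[0].id
peptides = bt.theoretical_peptides(proteome[pid])
print(f"{pid}: {len(proteome[pid])} residues -> "
      f"{len(peptides)} theoretical peptides of 7-40 aa")

ppm = bt.ppm_quantify(evidence, proteome, metadata)
ibaq = bt.ibaq_quantify(evidence, proteome, metadata)

sample = ppm.matrix.sample_ids[0]
print(f"\nsample {sample}:")
print(f"  ppm column sum      = {ppm.matrix.values[sample].sum():,.1f}  (always 1e6)")
print(f"  proteins quantified = {ppm.matrix.values[sample].notna().sum()}")
row = ppm.info.loc[pid]
print(f"  {pid}: correction factor {row['correction_factor']:.5f} "
      f"(1 / summed in-range peptide length), "
      f"ppm {ppm.matrix.values.loc[pid, sample]:,.0f}, "
      f"iBAQ {ibaq.matrix.values.loc[pid, sample]:,.0f}")

# between-sample median-ratio normalization of raw intensities
intensity = bt.intensity_matrix(evidence, proteome, metadata)
normalized, factors = bt.normalize_intensities(intensity)
print(f"\nmedian-ratio scaling factors: min {factors.min():.3f}, "
      f"max {factors.max():.3f} (1 = typical sample)")
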