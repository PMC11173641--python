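"""Simulate a metaproteomic protein-group table and apply the quality filters.

Generates one synthetic acetification profile (FL/DL/UL sampling times,
three biological replicates each, a Komagataeibacter-dominated community),
then applies the two retention rules: high FDR confidence with score >= 2
and >= 3 peptides, and detection in >= 50% of the replicates of at least
one sampling time.
"""

import acetoprot as ap

table, truth = ap.simulate(ap.SimConfig(seed=42))
print(f"simulated {len(table)} protein groups x {len(table.design)} samples")

filtered, report_id = ap.filter_identification(table)
print(f"identification filter removed {report_id.n_removed} "
      f"(confidence {report_id.n_removed_confidence}, "
      f"score {report_id.n_removed_score}, peptides {report_id.n_removed_peptides})")

retained, report_pres = ap.filter_replicate_presence(filtered)
print(f"replicate-presence filter removed {report_pres.n_removed_presence}; "
      f"{len(retained)} protein groups retained")

# exclusivity between two sampling times: present in >=50% of one group's
# replicates and absent from every replicate of the other
only_fl, only_ul = ap.exclusive_proteins(retained, ("SY", "FL"), ("SY", "UL"))
print(f"exclusive to FL: {len(only_fl)}, exclusive to UL: {len(only_ul)} "
      "(omitted from pairwise shared totals)")
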