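"""Score questionnaire items into the attraction-vector representation.

Builds a tiny item table for three participants, applies the 75%-response
scoring rule, and converts the androphilia/gynephilia means into strength
(vector magnitude) and degree (phase in degrees) of sexual attraction.
"""

import pandas as pd

from cortexmicro import psychosex

rows = []
for pid, group, a_item, g_item, q_item in [
    ("P001", "cis_boy", 1, 5, 5),    # exclusively gynephilic, no dysphoria
    ("P002", "cis_girl", 4, 1, 5),   # strongly androphilic, no dysphoria
    ("P003", "gd_afab", 2, 4, 2),    # gynephilic-leaning, dysphoric range
]:
    row = {"id": pid, "group": group, "age_months": 180}
    row.update({f"eros_a{i}": a_item for i in range(1, 9)})
    row.update({f"eros_g{i}": g_item for i in range(1, 9)})
    row.update({f"gidyq{i}": q_item for i in range(1, 28)})
    rows.append(row)

records = psychosex.load_participants(pd.DataFrame(rows))
table = psychosex.participants_frame(records)
print(table[["id", "group", "strength", "degree", "gidyq_mean", "gd_flag"]]
      .round(2).to_string(index=False))
print()
print("strength is the vector length sqrt(a^2 + g^2) in [1.41, 7.07]; "
      "degree is the phase in degrees (11 = exclusively androphilic, "
      "79 = exclusively gynephilic, 45 = equal); gd_flag marks a GIDYQ-AA "
      "mean below the 3.00 screening threshold.")
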