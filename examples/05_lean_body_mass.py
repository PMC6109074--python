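"""Lean body mass from micro-CT adipose volumetry.

LBM (g) = body weight (g) - adipose volume (cm^3) x 0.9 (g/cm^3).
"""

import pandas as pd

from permdeg import add_lean_body_mass, lean_body_mass

print(f"single animal: LBM(40 g, 10 cm^3) = {lean_body_mass(40.0, 10.0)} g")

cohort = pd.DataFrame(
    {
        "id": ["wt_1", "wt_2", "ko_1", "ko_2"],
        "body_weight_g": [42.1, 39.5, 33.2, 34.8],
        "adipose_volume_cm3": [12.4, 10.9, 4.1, 5.0],
    }
)
print(add_lean_body_mass(cohort))
print("-> lbm_g subtracts the fat mass implied by the segmented volume")
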