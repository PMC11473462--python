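"""Derive the five body-composition indices from raw tissue volumes.

The indices normalise tissue volumes against bone (sarcopenia, fat,
mediastinal fat), against total adipose tissue (myosteatosis) or against
lung volume (pulmonary fat index), making them comparable across body
sizes: scaling every volume of a subject by the same factor leaves all
five unchanged.
"""

from ctbca import BCAVolumes, compute_indices

vols = BCAVolumes(
    bone_ml=1000.0,     # thoracic bone
    muscle_ml=1800.0,   # thoracic muscle
    sat_ml=100.0,       # subcutaneous adipose tissue
    vat_ml=50.0,        # visceral adipose tissue
    imat_ml=10.0,       # inter-/intra-muscular adipose tissue
    eat_ml=5.0,         # epicardial adipose tissue
    mat_ml=35.0,        # mediastinal adipose tissue
    lung_ml=100.0,
    ctpfav_ml=2.06,     # pulmonary fat attenuation volume
    tat_ml=200.0,       # total adipose = SAT+VAT+IMAT+EAT+MAT
)

panel = compute_indices(vols)
print("sarcopenia index      (muscle/bone):   ", round(panel.sarcopenia_index, 2))
print("fat index             (TAT/bone):      ", round(panel.fat_index, 2))
print("myosteatosis index    (100*IMAT/TAT):  ", round(panel.myosteatosis_index, 2), "%")
print("mediastinal fat index (MAT/bone):      ", round(panel.mediastinal_fat_index, 3))
print("pulmonary fat index   (100*CTpfav/lung):", round(panel.pulmonary_fat_index, 2), "%")
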