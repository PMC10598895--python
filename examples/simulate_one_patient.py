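"""Simulate a single patient and print the expected glottal visibility.

Builds one bedside measurement record, runs the geometric laryngoscopy
simulation and prints V with both screening calls.  A positive V is the
length (mm) of the glottal anteroposterior span the line of sight reaches,
measured from the posterior commissure; a negative V is how far (mm) the
best achievable sight line misses the posterior commissure.
"""

from gadas import classify, simulate_patient, validate_record

patient = validate_record(
    {
        "sex": "female",
        "age": 58,
        "height": 162,
        "weight": 65,
        "mouth_opening": 3.6,  # cm
        "mallampati": 3,
        "thyromental": 6.8,  # cm
        "head_up_grade": 2,
        "tongue_thickness": 6.2,  # cm
        "hyomental": 4.9,  # cm
        "tmj_rom": 10.0,  # mm
        "small_mandible": False,
    }
)

result = simulate_patient(patient)
calls = classify(result.visibility_mm)

print(f"expected glottal visibility V = {result.visibility_rounded:.1f} mm")
print(f"sight line reaches the cords:  {result.intersects_cords}")
print(f"difficult laryngoscopy call (V <= -1 mm): {calls.difficult_laryngoscopy_pred}")
print(f"difficult intubation call  (V <= -4 mm):  {calls.difficult_intubation_pred}")
print()
print(
    "A V this low means the tangent sight line over the compressed tongue\n"
    "passes dorsal of the posterior commissure by |V| mm: the glottis is\n"
    "predicted to be partially or fully hidden at direct laryngoscopy."
)
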