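"""Render two patients at a shared scale as SVG schematics.

Simulates a favourable and an unfavourable patient, renders both sagittal
scenes with one common viewport (so the drawings are directly comparable),
and writes the SVG files next to this script.
"""

from pathlib import Path

from gadas import Viewport, glottal_visibility, render_scene, simulate_scene, validate_record

base = dict(
    sex="male", age=45, weight=75, mallampati=1, hyomental=5.5, small_mandible=False
)
favourable = validate_record(
    dict(base, height=180, mouth_opening=4.5, thyromental=9.0, head_up_grade=1,
         tongue_thickness=5.5, tmj_rom=15)
)
unfavourable = validate_record(
    dict(base, height=160, mouth_opening=3.2, thyromental=7.0, head_up_grade=2,
         tongue_thickness=7.0, tmj_rom=5)
)

scenes = [simulate_scene(r) for r in (favourable, unfavourable)]
results = [glottal_visibility(s) for s in scenes]
viewport = Viewport.for_scenes(scenes)  # one scale for both drawings

out_dir = Path(__file__).parent
for name, scene, res in zip(("favourable", "unfavourable"), scenes, results):
    path = out_dir / f"scene_{name}.svg"
    path.write_text(render_scene(scene, res, viewport))
    print(f"{name}: V = {res.visibility_rounded:.1f} mm -> {path.name}")

print()
print("Open the SVGs side by side: the green dashed line is the limiting\n"
      "sight ray from the upper incisor apex; the orange span on the blue\n"
      "glottal segment is the visible portion of the cords (absent when V < 0).")
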