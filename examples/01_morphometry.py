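"""Airway cross-section morphometry: Cr, Dave and Dh from printed calibres.

Builds elliptic lumens matching the circularity (Cr) and average diameter
(Dave) reported for the right main bronchus (RMB) and the right-upper-lobe
trifurcation (TriRUL) of two healthy subjects and two severe asthmatics,
then evaluates the hydraulic diameter Dh = 4 Ac / Pe = Cr x Dave.
"""

from aerotree import compute_cr, compute_dave, compute_dh, elliptic_section_from

SUBJECTS = {
    # (Cr, Dave mm) printed per subject
    "RMB": {"HS 1": (0.974, 12.8), "HS 2": (0.962, 14.1),
            "SA 1": (0.926, 15.9), "SA 2": (0.927, 12.5)},
    "TriRUL": {"HS 1": (0.953, 8.3), "HS 2": (0.959, 8.2),
               "SA 1": (0.883, 8.5), "SA 2": (0.820, 6.1)},
}

print(f"{'branch':8s} {'subject':8s} {'Cr':>6s} {'Dave_mm':>8s} {'Dh_mm':>6s}")
for branch, rows in SUBJECTS.items():
    for subject, (cr, dave_mm) in rows.items():
        cs = elliptic_section_from(cr, dave_mm * 1e-3)
        print(
            f"{branch:8s} {subject:8s} {compute_cr(cs):6.3f} "
            f"{compute_dave(cs)*1e3:8.1f} {compute_dh(cs)*1e3:6.1f}"
        )

print(
    "\nDh combines narrowing (Dave) with non-circularity (Cr): the severe"
    "\nasthmatics' TriRUL loses ~1 mm of effective calibre to lumen"
    "\nflattening alone (SA 1), and a further ~2 mm to narrowing (SA 2)."
)
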