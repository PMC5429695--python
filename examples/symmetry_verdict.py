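"""Single- vs dual-binding-mode classification from internal symmetry.

A dockerin supports the dual binding mode only when rotating it 180° about
its internal two-fold leaves compatible residues at every cohesin-contacting
position.  The symmetric fixture passes; substituting one contact-position
mate from valine to glutamine (nonpolar -> polar) breaks the second
interface and flips the verdict to single.
"""

from cohdoc import (
    DockerinSpec,
    analyze_complex,
    make_asymmetric_dockerin,
    make_cohesin_plateau,
    make_symmetric_dockerin,
)


def verdict_for(structure, spec):
    complex_ = make_cohesin_plateau(structure, spec)
    report = analyze_complex(complex_, "D", "C")
    sym = report["symmetry"]
    print(f"  internal rmsd {sym['internal_rmsd']:.3f} Å, "
          f"rotation {sym['rotation_angle']:.1f}°")
    for pair in sym["mate_pairs"]:
        if pair["is_contact_position"]:
            print(f"  contact {pair['position_name']}{pair['position']} -> "
                  f"{pair['mate_name']}{pair['mate']}: {pair['compatibility']}")
    print(f"  verdict: {report['verdict']}")


spec = DockerinSpec()
print("exactly duplicated repeats:")
verdict_for(make_symmetric_dockerin(spec), spec)

print()
spec_mut = DockerinSpec(substitutions=[(17, "Q")])
print("contact-position mate substituted V -> Q:")
verdict_for(make_asymmetric_dockerin(spec_mut), spec_mut)
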