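"""Calcium-site detection and EF-hand-like pattern classification.

Each repeat of the synthetic dockerin carries one Ca²⁺ with the canonical
n, n+2, n+4, n+11 coordination offsets plus one water — the arrangement
seen in the N-terminal repeat of enzyme-borne dockerins.
"""

from cohdoc import (
    classify_coordination_pattern,
    detect_calcium_sites,
    make_symmetric_dockerin,
)

structure = make_symmetric_dockerin()
chain = structure.chain("D")

for site in detect_calcium_sites(structure, chain):
    call = classify_coordination_pattern(site)
    print(f"Ca ion {site.ion_auth_number}: pattern = {call.pattern}")
    print(f"  offsets {site.offsets}, waters {site.water_count}")
    for auth, resname, atom, dist in site.coordinating_residues:
        print(f"  {resname}{auth}.{atom}  {dist:.2f} Å")
print()
print("offsets are auth-number distances from the first ligating residue;")
print("{0,2,4,11}+water is the canonical arrangement, {0,6,12}+water atypical.")
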