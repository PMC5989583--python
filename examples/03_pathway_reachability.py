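"""Which carotenoids can a given enzyme complement make?

Reachability over the enzyme-gated pathway graph: a compound is producible
iff a chain of reactions with fully present enzyme requirements connects it
to the IPP/DMAPP precursor pool.  Terminal compounds (no onward reaction
available) approximate what the cell accumulates.
"""

from crtprofiler import producible

cases = {
    "crtE only (non-carotenogenic)": {"IDI", "CrtE"},
    "core (zeaxanthin producer)": {"IDI", "CrtE", "CrtB", "CrtI", "CrtY", "CrtZ"},
    "group I (+CrtG)": {"IDI", "CrtE", "CrtB", "CrtI", "CrtY", "CrtZ", "CrtG"},
    "group III (+CrtW)": {"IDI", "CrtE", "CrtB", "CrtI", "CrtY", "CrtZ", "CrtW"},
    "group II (+CrtG+CrtW)": {"IDI", "CrtE", "CrtB", "CrtI", "CrtY", "CrtZ", "CrtG", "CrtW"},
}

for name, enzymes in cases.items():
    prod, terminals = producible(enzymes)
    print(f"{name}:")
    print(f"  terminal: {', '.join(sorted(terminals)) or '(nothing beyond precursors)'}")

# GGPP alone is colourless; CrtG pushes zeaxanthin to nostoxanthin (yellow),
# CrtW to astaxanthin (red), and both together add erythroxanthin and
# 2,2'-dihydroxycanthaxanthin (orange strains).
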