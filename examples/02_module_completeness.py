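"""Call module completeness from KO annotations.

A module is an ordered list of reactions; each reaction is satisfied by
any one of its alternatives (a set of KOs that must all be present).  A
module is complete when every reaction is satisfied — or all but one, in
modules with at least three reactions, to absorb annotation gaps.
"""

from traitatlas import KOAnnotationTable, ModuleDefinition
from traitatlas.modules import call_all, calls_table

defs = [
    # 3-reaction pathway; the third reaction needs a two-subunit complex
    ModuleDefinition("M_path", [
        [["K00001"], ["K00002"]],
        [["K00003"]],
        [["K00004", "K00005"]],
    ]),
    # 2-reaction transporter: no tolerance below three reactions
    ModuleDefinition("M_pump", [[["K00010"]], [["K00011"]]]),
]

ko = KOAnnotationTable({
    "genome_full":   {"K00002", "K00003", "K00004", "K00005", "K00010", "K00011"},
    "genome_gap":    {"K00001", "K00003"},            # 2/3 reactions: tolerated
    "genome_broken": {"K00004", "K00010"},            # complex incomplete
})

print(calls_table(call_all(defs, ko)).to_string(index=False))
print()
print("genome_gap carries M_path with one missing reaction (2/3): complete.")
print("genome_broken has only half of the K00004+K00005 complex and half of "
      "M_pump: both incomplete.")
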