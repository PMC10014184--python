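"""Gene-reaction associations for the mouse carnitine shuttle and
mitochondrial beta-oxidation pathway.

These are the published gene-protein-reaction rules (Mouse1 reaction
identifiers, MGI gene symbols) for the cytosolic fatty-acid activation,
carnitine shuttle and mitochondrial beta-oxidation steps highlighted by
the flux analysis.  The synthetic toy network mirrors their OR/AND
structure with synthetic gene symbols; the real symbols are kept here as
reference annotation.
"""

from __future__ import annotations

from .gpr import gpr_genes

__all__ = ["CARNITINE_BETA_OXIDATION_GPRS", "PATHWAY_OF_REACTION", "unique_pathway_genes"]

#: Mouse1 reaction id -> published GPR rule.
CARNITINE_BETA_OXIDATION_GPRS: dict[str, str] = {
    "MAR00255": ("Acsbg1 or Acsbg2 or Acsl1 or Acsl3 or Acsl4 or Acls5 "
                 "or Acsl6 or Meikin or Slc27a2"),
    "MAR02657": "Cpt1a or Cpt1b or Cpt1c",
    "MAR00110": "Slc25a20",
    "MAR02592": "Slc25a20 or Slc25a29",
    "MAR03226": "Acad9 or Acadl or Acadm or Acadvl",
    "MAR03227": "Echs1 and Ehhadh and Hadha",
    "MAR03228": "Hadh and Hadha and Hsd17b10",
    "MAR03229": "Acaa2 and Hadha and Hadhb",
    "MAR02635": "Cpt2 or Crat",
}

#: Pathway assignment of each annotated reaction.
PATHWAY_OF_REACTION: dict[str, str] = {
    "MAR00255": "fatty acid activation (cytosol)",
    "MAR02657": "carnitine shuttle (cytosol)",
    "MAR00110": "fatty acid oxidation",
    "MAR02592": "carnitine shuttle (mitochondria)",
    "MAR03226": "beta-oxidation of unsaturated fatty acids (mitochondria)",
    "MAR03227": "beta-oxidation of unsaturated fatty acids (mitochondria)",
    "MAR03228": "beta-oxidation of unsaturated fatty acids (mitochondria)",
    "MAR03229": "beta-oxidation of unsaturated fatty acids (mitochondria)",
    "MAR02635": "carnitine shuttle (mitochondria)",
}


def unique_pathway_genes() -> set[str]:
    """Unique gene symbols across all annotated reaction rules."""
    genes: set[str] = set()
    for rule in CARNITINE_BETA_OXIDATION_GPRS.values():
        genes |= gpr_genes(rule)
    return genes
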