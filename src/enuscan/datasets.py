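"""Bundled in-package datasets.

The package ships three small fixtures transcribed from the screen's
published record — the 16-candidate genotype/phenotype panel, the
chromosome-12 backcross disassociation variant table, and the 13-residue
transactivation-domain peptide reconstructed by translating the published
site-directed mutagenesis primers — plus the Chou & Fasman (1978) alpha-helix
propensity constants.
"""

from __future__ import annotations

from importlib import resources

from .io import read_panel, read_peptides, read_variant_table
from .types import SegregationPanel


def _data_path(name: str):
    return resources.files("enuscan.data").joinpath(name)


def load_candidate_panel() -> SegregationPanel:
    """The 16-variant x 12-mouse (7 affected, 5 unaffected) Sanger panel."""
    with resources.as_file(_data_path("candidate_panel.tsv")) as p:
        return read_panel(p)


def load_backcross_variants():
    """The four chromosome-12 variants genotyped in the G10 backcross animal."""
    with resources.as_file(_data_path("backcross_variants.tsv")) as p:
        return read_variant_table(p, dialect="tsv")


def load_ta_domain_peptide():
    """The wildtype TA-domain 13-mer (protein residues 185-197), with offset.

    Returns ``(record_id, sequence, offset)``.
    """
    with resources.as_file(_data_path("ta_domain.fa")) as p:
        rid, seq = read_peptides(p)[0]
    offset = int(rid.split("_")[1])
    return rid, seq, offset


def load_propensity_values(name: str = "chou_fasman_alpha") -> dict:
    """Per-residue propensity constants from a bundled scale file."""
    values = {}
    with resources.as_file(_data_path(f"{name}.tsv")) as p:
        with open(p, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("aa\t"):
                    continue
                aa, val = line.split("\t")
                values[aa] = float(val)
    return values
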