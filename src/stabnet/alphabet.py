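"""The 20-letter amino-acid alphabet shared by every sequence-facing module."""

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_RESIDUES = len(AMINO_ACIDS)


def is_standard(residue: str) -> bool:
    return residue in AA_INDEX
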