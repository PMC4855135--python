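"""Named presets: Accumulibacter ppk1 clade labels and published primer sets.

The Accumulibacter lineage is subdivided on the polyphosphate kinase 1
(ppk1) marker into Type I (Clades IA–IE) and Type II (Clades IIA–II-I).
``ACCUMULIBACTER_PRIMERS`` carries the clade-specific ppk1 qPCR primer
sets designed against that lineage, named ``<gene>-<pos><f|r>`` where
``pos`` is the primer's reference coordinate (forward: 5'-most template
position; reverse: rightmost template position of the amplicon).
"""

from __future__ import annotations

from .insilico import Primer, PrimerPair

__all__ = ["ACCUMULIBACTER_CLADES", "ACCUMULIBACTER_PRIMERS", "accumulibacter_pair"]

ACCUMULIBACTER_CLADES: tuple[str, ...] = (
    "IA", "IB", "IC", "ID", "IE",
    "IIA", "IIB", "IIC", "IID", "IIE", "IIF", "IIG", "IIH", "II-I",
)

# primer set -> (target clade, forward (name, seq), reverse (name, seq))
ACCUMULIBACTER_PRIMERS: dict[str, tuple[str, tuple[str, str], tuple[str, str]]] = {
    "Primer-IA": (
        "IA",
        ("Acc-ppk1-974f", "TGATGCGCGACAATCTCAAATTCAA"),
        ("Acc-ppk1-1113r", "AATGATCGGATTGAAGCTCTGGTAG"),
    ),
    "Primer-IB": (
        "IB",
        ("Acc-ppk1-372f", "TGAAGGCATTCGCTTCCT"),
        ("Acc-ppk1-653r", "AAGCAGTATTCGCTGTC"),
    ),
    "Primer-IC": (
        "IC",
        ("Acc-ppk1-362f", "AGCTGGCGAGTGAAGGCATTCG"),
        ("Acc-ppk1-758r", "AACAGGTTGCTGTTGCGCGTGA"),
    ),
    "Primer-ID": (
        "ID",
        ("Acc-ppk1-634f", "TGCGACAGCGAATACAG"),
        ("Acc-ppk1-848r", "ACTTCGAGGCGGACG"),
    ),
    "Primer-IIE": (
        "IIE",
        ("Acc-ppk1-757f", "TTCGTGGACGAGGAAGA"),
        ("Acc-ppk1-1129r", "ATTGTTCGAGCAACTCGATG"),
    ),
    "Primer-IIG": (
        "IIG",
        ("Acc-ppk1-410f", "CCGAGCAACGCGAATGG"),
        ("Acc-ppk1-514r", "TGTTGAGTACGCGCGGGA"),
    ),
    "Primer-IIH": (
        "IIH",
        ("Acc-ppk1-701f", "ACTCCTTCGTATTCCTCTCT"),
        ("Acc-ppk1-928r", "TCATCGCTTCGGAGCA"),
    ),
    "Primer-II-I": (
        "II-I",
        ("Acc-ppk1-688f", "AGTGATTATGCTTTCGTCTTTC"),
        ("Acc-ppk1-946r", "TGAACTGTCCGAGCAGGA"),
    ),
}


def accumulibacter_pair(primer_set: str) -> PrimerPair:
    """Build the :class:`PrimerPair` for a named Accumulibacter primer set."""
    clade, (fname, fseq), (rname, rseq) = ACCUMULIBACTER_PRIMERS[primer_set]
    return PrimerPair(primer_set, Primer.from_name(fname, fseq), Primer.from_name(rname, rseq))
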