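"""Bundled worked-example data: the Queensland fruit fly COI LAMP assay.

The six-primer set targeting the 5' COI barcode region of *Bactrocera
tryoni* (Queensland fruit fly) and its validated instrument programs serve
as the package's regression fixture and README example.  The FIP/BIP
fusion points follow the assay's architecture: FIP = F1c(22) + F2(22),
BIP = B1c(22) + B2(29).  Region spans are in the coordinate frame of the
*B. tryoni* mitogenome barcode window (positions 1889-2187).
"""

from __future__ import annotations

from .assay import ProtocolProgram, hold, ramp
from .iupac import reverse_complement
from .primers import LampPrimer, LampPrimerSet, PrimerRegion

_FIP = "TGAGATACCAGCTAAGTGAAGTGATATCGTCTGTTATTGCACAC"
_BIP = "ATACGATCTACAGGRATTTCGTTTGAAAACTGGCARTGAYAGTAAAAGTAA"


def qff_primer_set() -> LampPrimerSet:
    """The *B. tryoni* (Queensland fruit fly) COI LAMP primer set.

    F3/B3 outer, FIP/BIP inner (44 and 51 nt fusions), FL/BL loop primers.
    BIP carries two R and one Y ambiguity (degeneracy 8) covering known
    within-complex variation; all other primers are non-degenerate.
    """
    f1 = PrimerRegion(name="F1", span=(0, 22), strand="plus",
                      sequence=reverse_complement(_FIP[:22]))
    f2 = PrimerRegion(name="F2", span=(0, 22), strand="plus", sequence=_FIP[22:])
    b1 = PrimerRegion(name="B1", span=(0, 22), strand="minus",
                      sequence=reverse_complement(_BIP[:22]))
    b2 = PrimerRegion(name="B2", span=(0, 29), strand="minus", sequence=_BIP[22:])
    return LampPrimerSet(
        name="Btryoni-COI-LAMP",
        f3=LampPrimer(label="Btryoni_F3", sequence="TACAGGTTGAACAGTTTACCCAC"),
        b3=LampPrimer(label="Btryoni_B3", sequence="CAGGGTCAAAAAAGGAGGTATT"),
        fip=LampPrimer(label="Btryoni_FIP", sequence=_FIP),
        bip=LampPrimer(label="Btryoni_BIP", sequence=_BIP),
        lf=LampPrimer(label="Btryoni_FL", sequence="TAAATCAACTGAAGCCCCTCC"),
        lb=LampPrimer(label="Btryoni_BL", sequence="CCTCTTTTCGTTTGAGCAGTTGTATT"),
        fip_parts=(f1, f2),
        bip_parts=(b1, b2),
    )


#: published predicted annealing temperatures (°C) for the assay's primers
QFF_PREDICTED_TM = {
    "Btryoni_F3": 60.3, "Btryoni_B3": 57.7, "Btryoni_FIP": 71.4,
    "Btryoni_BIP": 70.4, "Btryoni_FL": 60.3, "Btryoni_BL": 59.8,
}

#: expected anneal-derivative temperature of the assay's product (°C)
QFF_EXPECTED_ANNEAL_C = 82.5


def quickextract_program() -> ProtocolProgram:
    """Crude whole-specimen DNA extraction: 65 °C 6 min, 98 °C 2 min."""
    return ProtocolProgram(steps=[hold(65, 6), hold(98, 2)])


def lamp_program() -> ProtocolProgram:
    """Isothermal amplification at 65 °C for 25 min, then an annealing-curve
    analysis ramping 98 -> 73 °C at 0.05 °C/s."""
    return ProtocolProgram(steps=[hold(65, 25), ramp(98, 73, "0.05")])
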