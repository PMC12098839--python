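"""TMTpro 18-plex reporter-channel reference table.

The 18 reporter ions fall in m/z 126-136 and differ by combinations of
13C and 15N substitutions on the C8H16N+ reporter fragment.  Channels that
share a nominal mass ("N"/"C" pairs, e.g. 130N/130C) differ only by a
15N-vs-13C substitution and are separated by ~0.0063 Da; resolving such a
pair requires a resolving power of roughly 45,000 at this m/z.

Exact masses are compiled constants from the vendor reagent documentation.
They agree with the isotope-substitution arithmetic

    exact_mz = mz(126) + n13C * (m13C - m12C) + n15N * (m15N - m14N)

which the test suite uses as an independent oracle.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "ReporterChannel",
    "reporter_table",
    "pair_spacing",
    "channel_labels",
    "exact_mz",
    "write_reference_tsv",
]

# CODATA/AME isotope masses used only by the documentation above and the
# test oracle; the channel m/z values themselves are vendor constants.
M_12C = 12.0
M_13C = 13.00335483507
M_14N = 14.00307400443
M_15N = 15.00010889888


@dataclass(frozen=True)
class ReporterChannel:
    """One TMTpro reporter channel.

    Attributes
    ----------
    label : str
        Channel name, e.g. ``"126"``, ``"127N"``, ``"130C"``.
    nominal_mass : int
        Integer Da of the reporter ion.
    exact_mz : float
        Monoisotopic singly-charged reporter m/z in Da.
    heavy_isotope : str
        ``"13C"``, ``"15N"`` or ``"none"`` — which substitution
        distinguishes this channel from its same-nominal-mass partner.
    partner_label : str or None
        Label of the isotopolog partner sharing the nominal mass, or None
        for the two unpaired channels (126 and 135N).
    """

    label: str
    nominal_mass: int
    exact_mz: float
    heavy_isotope: str
    partner_label: Optional[str]


# (label, n 13C substitutions, n 15N substitutions, vendor exact m/z).
# Channels listed in ascending m/z; N channels carry one 15N, C channels
# one extra 13C relative to their partner.
_CHANNEL_DEFS = (
    ("126", 0, 0, 126.127726),
    ("127N", 0, 1, 127.124761),
    ("127C", 1, 0, 127.131081),
    ("128N", 1, 1, 128.128116),
    ("128C", 2, 0, 128.134436),
    ("129N", 2, 1, 129.131471),
    ("129C", 3, 0, 129.137790),
    ("130N", 3, 1, 130.134825),
    ("130C", 4, 0, 130.141145),
    ("131N", 4, 1, 131.138180),
    ("131C", 5, 0, 131.144500),
    ("132N", 5, 1, 132.141535),
    ("132C", 6, 0, 132.147855),
    ("133N", 6, 1, 133.144890),
    ("133C", 7, 0, 133.151210),
    ("134N", 7, 1, 134.148245),
    ("134C", 8, 0, 134.154565),
    ("135N", 8, 1, 135.151600),
)


def _build_table() -> tuple[ReporterChannel, ...]:
    by_nominal: dict[int, list[str]] = {}
    for label, _, _, mz in _CHANNEL_DEFS:
        by_nominal.setdefault(int(round(mz)), []).append(label)
    channels = []
    for label, n13c, n15n, mz in _CHANNEL_DEFS:
        nominal = int(round(mz))
        partners = [l for l in by_nominal[nominal] if l != label]
        partner = partners[0] if partners else None
        if partner is None:
            heavy = "none"
        elif label.endswith("N"):
            heavy = "15N"
        else:
            heavy = "13C"
        channels.append(
            ReporterChannel(
                label=label,
                nominal_mass=nominal,
                exact_mz=mz,
                heavy_isotope=heavy,
                partner_label=partner,
            )
        )
    return tuple(channels)


_TABLE = _build_table()
_BY_LABEL = {c.label: c for c in _TABLE}


def reporter_table() -> tuple[ReporterChannel, ...]:
    """Return the 18 TMTpro reporter channels in ascending m/z order.

    The table is immutable and identical on every call.
    """
    return _TABLE


def channel_labels() -> tuple[str, ...]:
    """The 18 channel labels in ascending m/z order."""
    return tuple(c.label for c in _TABLE)


def exact_mz(label: str) -> float:
    """Exact reporter m/z for a channel label.

    Raises
    ------
    KeyError
        If the label is not one of the 18 TMTpro channels.
    """
    return _BY_LABEL[label].exact_mz


def pair_spacing(label: str) -> float:
    """m/z spacing of the isotopolog pair containing ``label``.

    Returns ``exact_mz(13C member) - exact_mz(15N member)`` for the pair
    sharing that channel's nominal mass; always positive (~0.0063 Da).

    Raises
    ------
    ValueError
        If the channel has no same-nominal-mass partner (126 or 135N).
    """
    try:
        chan = _BY_LABEL[label]
    except KeyError:
        raise KeyError(f"unknown TMTpro channel label: {label!r}") from None
    if chan.partner_label is None:
        raise ValueError(f"channel {label!r} has no isotopolog partner")
    partner = _BY_LABEL[chan.partner_label]
    c_member = chan if chan.heavy_isotope == "13C" else partner
    n_member = partner if chan.heavy_isotope == "13C" else chan
    return c_member.exact_mz - n_member.exact_mz


def isotopolog_pairs() -> tuple[tuple[ReporterChannel, ReporterChannel], ...]:
    """The 8 same-nominal-mass (15N member, 13C member) channel pairs."""
    pairs = []
    for chan in _TABLE:
        if chan.heavy_isotope == "15N" and chan.partner_label is not None:
            pairs.append((chan, _BY_LABEL[chan.partner_label]))
    return tuple(pairs)


def write_reference_tsv(stream=None) -> None:
    """Write the reference table as TSV (label, nominal_mass, exact_mz,
    partner) for audit; defaults to stdout."""
    out = stream if stream is not None else sys.stdout
    out.write("label\tnominal_mass\texact_mz\tpartner\n")
    for c in _TABLE:
        partner = c.partner_label if c.partner_label is not None else "NA"
        out.write(f"{c.label}\t{c.nominal_mass}\t{c.exact_mz:.6f}\t{partner}\n")
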