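"""Discrete filter banks for the ten mother wavelets used in the pipeline.

A mother wavelet is realised discretely as a quadrature filter bank: a
low-pass (scaling) and a high-pass (wavelet) decomposition filter, plus the
corresponding reconstruction pair.  Tap values are the standard published
double-precision tables, stored here as literals so the transform has no
runtime dependency on any external wavelet library.

Supported identifiers: ``db1``, ``db2``, ``db4`` (Daubechies), ``coif1``,
``coif5`` (Coiflets), ``bior2.2``, ``bior3.3`` (biorthogonal splines) and
``sym2``, ``sym3``, ``sym5`` (Symlets).  The alias spellings ``sim2``,
``sim3``, ``sim5`` and the dot-free ``bior22``/``bior33`` are accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["FilterBank", "filter_bank", "WAVELETS"]

#: Canonical identifiers, in the fixed order used for feature extraction.
WAVELETS: tuple[str, ...] = (
    "db1",
    "db2",
    "db4",
    "coif1",
    "coif5",
    "bior2.2",
    "bior3.3",
    "sym2",
    "sym3",
    "sym5",
)

# name -> (dec_lo, dec_hi, rec_lo, rec_hi, orthogonal)
_TABLE: dict[str, tuple[tuple[float, ...], tuple[float, ...], tuple[float, ...], tuple[float, ...], bool]] = {
    "db1": (
        (0.7071067811865476, 0.7071067811865476),
        (-0.7071067811865476, 0.7071067811865476),
        (0.7071067811865476, 0.7071067811865476),
        (0.7071067811865476, -0.7071067811865476),
        True,
    ),
    "db2": (
        (-0.12940952255126037, 0.2241438680420134, 0.8365163037378079, 0.48296291314453416),
        (-0.48296291314453416, 0.8365163037378079, -0.2241438680420134, -0.12940952255126037),
        (0.48296291314453416, 0.8365163037378079, 0.2241438680420134, -0.12940952255126037),
        (-0.12940952255126037, -0.2241438680420134, 0.8365163037378079, -0.48296291314453416),
        True,
    ),
    "db4": (
        (-0.010597401785069032, 0.0328830116668852, 0.030841381835560764, -0.18703481171909309,
         -0.027983769416859854, 0.6308807679298589, 0.7148465705529157, 0.2303778133088965),
        (-0.2303778133088965, 0.7148465705529157, -0.6308807679298589, -0.027983769416859854,
         0.18703481171909309, 0.030841381835560764, -0.0328830116668852, -0.010597401785069032),
        (0.2303778133088965, 0.7148465705529157, 0.6308807679298589, -0.027983769416859854,
         -0.18703481171909309, 0.030841381835560764, 0.0328830116668852, -0.010597401785069032),
        (-0.010597401785069032, -0.0328830116668852, 0.030841381835560764, 0.18703481171909309,
         -0.027983769416859854, -0.6308807679298589, 0.7148465705529157, -0.2303778133088965),
        True,
    ),
    "coif1": (
        (-0.015655728135791993, -0.07273261951252645, 0.3848648468648578,
         0.8525720202116004, 0.3378976624574818, -0.07273261951252645),
        (0.07273261951252645, 0.3378976624574818, -0.8525720202116004,
         0.3848648468648578, 0.07273261951252645, -0.015655728135791993),
        (-0.07273261951252645, 0.3378976624574818, 0.8525720202116004,
         0.3848648468648578, -0.07273261951252645, -0.015655728135791993),
        (-0.015655728135791993, 0.07273261951252645, 0.3848648468648578,
         -0.8525720202116004, 0.3378976624574818, 0.07273261951252645),
        True,
    ),
    "coif5": (
        (-9.604010112767894e-08, -1.6237995172048338e-07, 2.0612203985788783e-06,
         3.7007277113394796e-06, -2.1270221672515614e-05, -4.12198619242655e-05,
         0.00014035632812373243, 0.0003018579416682448, -0.0006375589261258812,
         -0.0016616273039298788, 0.0024315754425382886, 0.006761520220620417,
         -0.009159507338676163, -0.019758391600965465, 0.032674799467057355,
         0.041287530472117834, -0.10556315130733723, -0.06203775157498196,
         0.4379823066591634, 0.7742936228603274, 0.42157126673075435,
         -0.052046670253554764, -0.09192158806008609, 0.028169744270532353,
         0.023408322118927783, -0.010131584846900276, -0.00415931262757864,
         0.0021782943778456947, 0.0003585777411617577, -0.000212081862067494),
        (0.000212081862067494, 0.0003585777411617577, -0.0021782943778456947,
         -0.00415931262757864, 0.010131584846900276, 0.023408322118927783,
         -0.028169744270532353, -0.09192158806008609, 0.052046670253554764,
         0.42157126673075435, -0.7742936228603274, 0.4379823066591634,
         0.06203775157498196, -0.10556315130733723, -0.041287530472117834,
         0.032674799467057355, 0.019758391600965465, -0.009159507338676163,
         -0.006761520220620417, 0.0024315754425382886, 0.0016616273039298788,
         -0.0006375589261258812, -0.0003018579416682448, 0.00014035632812373243,
         4.12198619242655e-05, -2.1270221672515614e-05, -3.7007277113394796e-06,
         2.0612203985788783e-06, 1.6237995172048338e-07, -9.604010112767894e-08),
        (-0.000212081862067494, 0.0003585777411617577, 0.0021782943778456947,
         -0.00415931262757864, -0.010131584846900276, 0.023408322118927783,
         0.028169744270532353, -0.09192158806008609, -0.052046670253554764,
         0.42157126673075435, 0.7742936228603274, 0.4379823066591634,
         -0.06203775157498196, -0.10556315130733723, 0.041287530472117834,
         0.032674799467057355, -0.019758391600965465, -0.009159507338676163,
         0.006761520220620417, 0.0024315754425382886, -0.0016616273039298788,
         -0.0006375589261258812, 0.0003018579416682448, 0.00014035632812373243,
         -4.12198619242655e-05, -2.1270221672515614e-05, 3.7007277113394796e-06,
         2.0612203985788783e-06, -1.6237995172048338e-07, -9.604010112767894e-08),
        (-9.604010112767894e-08, 1.6237995172048338e-07, 2.0612203985788783e-06,
         -3.7007277113394796e-06, -2.1270221672515614e-05, 4.12198619242655e-05,
         0.00014035632812373243, -0.0003018579416682448, -0.0006375589261258812,
         0.0016616273039298788, 0.0024315754425382886, -0.006761520220620417,
         -0.009159507338676163, 0.019758391600965465, 0.032674799467057355,
         -0.041287530472117834, -0.10556315130733723, 0.06203775157498196,
         0.4379823066591634, -0.7742936228603274, 0.42157126673075435,
         0.052046670253554764, -0.09192158806008609, -0.028169744270532353,
         0.023408322118927783, 0.010131584846900276, -0.00415931262757864,
         -0.0021782943778456947, 0.0003585777411617577, 0.000212081862067494),
        True,
    ),
    "bior2.2": (
        (0.0, -0.1767766952966369, 0.3535533905932738, 1.0606601717798212,
         0.3535533905932738, -0.1767766952966369),
        (-0.0, 0.3535533905932738, -0.7071067811865476, 0.3535533905932738, -0.0, 0.0),
        (0.0, 0.3535533905932738, 0.7071067811865476, 0.3535533905932738, 0.0, 0.0),
        (0.0, 0.1767766952966369, 0.3535533905932738, -1.0606601717798212,
         0.3535533905932738, 0.1767766952966369),
        False,
    ),
    "bior3.3": (
        (0.06629126073623882, -0.1988737822087165, -0.15467960838455727, 0.9943689110435825,
         0.9943689110435825, -0.15467960838455727, -0.1988737822087165, 0.06629126073623882),
        (-0.0, 0.0, -0.1767766952966369, 0.5303300858899106,
         -0.5303300858899106, 0.1767766952966369, -0.0, 0.0),
        (0.0, 0.0, 0.1767766952966369, 0.5303300858899106,
         0.5303300858899106, 0.1767766952966369, 0.0, 0.0),
        (0.06629126073623882, 0.1988737822087165, -0.15467960838455727, -0.9943689110435825,
         0.9943689110435825, 0.15467960838455727, -0.1988737822087165, -0.06629126073623882),
        False,
    ),
    "sym2": (
        (-0.12940952255092145, 0.22414386804185735, 0.836516303737469, 0.48296291314469025),
        (-0.48296291314469025, 0.836516303737469, -0.22414386804185735, -0.12940952255092145),
        (0.48296291314469025, 0.836516303737469, 0.22414386804185735, -0.12940952255092145),
        (-0.12940952255092145, -0.22414386804185735, 0.836516303737469, -0.48296291314469025),
        True,
    ),
    "sym3": (
        (0.035226291882100656, -0.08544127388224149, -0.13501102001039084,
         0.4598775021193313, 0.8068915093133388, 0.3326705529509569),
        (-0.3326705529509569, 0.8068915093133388, -0.4598775021193313,
         -0.13501102001039084, 0.08544127388224149, 0.035226291882100656),
        (0.3326705529509569, 0.8068915093133388, 0.4598775021193313,
         -0.13501102001039084, -0.08544127388224149, 0.035226291882100656),
        (0.035226291882100656, 0.08544127388224149, -0.13501102001039084,
         -0.4598775021193313, 0.8068915093133388, -0.3326705529509569),
        True,
    ),
    "sym5": (
        (0.027333068345077982, 0.029519490925774643, -0.039134249302383094,
         0.1993975339773936, 0.7234076904024206, 0.6339789634582119,
         0.01660210576452232, -0.17532808990845047, -0.021101834024758855,
         0.019538882735286728),
        (-0.019538882735286728, -0.021101834024758855, 0.17532808990845047,
         0.01660210576452232, -0.6339789634582119, 0.7234076904024206,
         -0.1993975339773936, -0.039134249302383094, -0.029519490925774643,
         0.027333068345077982),
        (0.019538882735286728, -0.021101834024758855, -0.17532808990845047,
         0.01660210576452232, 0.6339789634582119, 0.7234076904024206,
         0.1993975339773936, -0.039134249302383094, 0.029519490925774643,
         0.027333068345077982),
        (0.027333068345077982, -0.029519490925774643, -0.039134249302383094,
         -0.1993975339773936, 0.7234076904024206, -0.6339789634582119,
         0.01660210576452232, 0.17532808990845047, -0.021101834024758855,
         -0.019538882735286728),
        True,
    ),
}

# accepted alias spellings -> canonical name
_ALIASES = {
    "sim2": "sym2",
    "sim3": "sym3",
    "sim5": "sym5",
    "bior22": "bior2.2",
    "bior33": "bior3.3",
    "haar": "db1",
}


@dataclass(frozen=True)
class FilterBank:
    """Decomposition/reconstruction tap sequences of one mother wavelet."""

    name: str
    dec_lo: np.ndarray
    dec_hi: np.ndarray
    rec_lo: np.ndarray
    rec_hi: np.ndarray
    orthogonal: bool

    @property
    def taps(self) -> int:
        return len(self.dec_lo)

    def __post_init__(self) -> None:
        for attr in ("dec_lo", "dec_hi", "rec_lo", "rec_hi"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))


def canonical_name(name: str) -> str:
    """Resolve aliases (``sim5`` → ``sym5``, ``bior22`` → ``bior2.2``)."""
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    if key not in _TABLE:
        raise ValueError(
            f"unknown wavelet {name!r}; supported: {', '.join(WAVELETS)} "
            "(aliases sim2/sim3/sim5, bior22/bior33)"
        )
    return key


def filter_bank(name: str) -> FilterBank:
    """Return the :class:`FilterBank` for a named mother wavelet.

    Parameters
    ----------
    name
        One of the ten supported identifiers or an accepted alias.

    Raises
    ------
    ValueError
        If the identifier is not recognised.
    """
    key = canonical_name(name)
    dec_lo, dec_hi, rec_lo, rec_hi, ortho = _TABLE[key]
    fb = FilterBank(key, np.array(dec_lo), np.array(dec_hi),
                    np.array(rec_lo), np.array(rec_hi), ortho)
    # paranoia: the literals must satisfy the quadrature sums
    assert abs(fb.dec_lo.sum() - math.sqrt(2)) < 1e-10
    assert abs(fb.dec_hi.sum()) < 1e-10
    return fb
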