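"""Published reference data used in worked examples and checks.

Official Hong Kong birth statistics by child category, 2006-2015: counts of
live births to a Mainland mother with a Hong Kong resident father (type A),
to two non-resident Mainland parents (type B), and all other local births.
Type B births collapse after 2012, when Mainland mothers were barred from
giving birth in Hong Kong hospitals.
"""

from __future__ import annotations

__all__ = ["HK_BIRTHS_BY_TYPE"]

#: year -> (type A births, type B births, other births)
HK_BIRTHS_BY_TYPE: dict[int, tuple[int, int, int]] = {
    2006: (9732, 16537, 65626),
    2007: (8067, 19198, 70875),
    2008: (7510, 25896, 78822),
    2009: (6404, 30597, 82095),
    2010: (6611, 34088, 88584),
    2011: (6426, 37023, 95451),
    2012: (5073, 27540, 91558),
    2013: (5025, 211, 57084),
    2014: (5777, 165, 62305),
    2015: (5191, 57, 59878),
}
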