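"""Compute 24 h milk production and infant intakes from a feed diary.

Builds a small hand-written test-weighing diary (weights in grams) and
derives the production and intake measures from it.
"""

from milksupply import (
    FeedDiary,
    FeedEvent,
    FeedKind,
    compute_intakes,
    compute_mp_24h,
)


def feed(end_h, vol_ml, kind=FeedKind.BREASTFEED, base=5200.0):
    end = end_h * 60
    return FeedEvent(end - 15, end, kind, base, base + vol_ml * 1.03)


diary = FeedDiary(
    "demo",
    [
        feed(0.0, 65),            # anchor feed: opens the window, not counted
        feed(3.5, 80),
        feed(7.0, 95),
        feed(11.0, 70),
        feed(15.5, 90),
        feed(19.0, 60),
        feed(22.0, 55, FeedKind.FORMULA_BOTTLE),
        feed(24.5, 85),
    ],
)

mp = compute_mp_24h(diary)
bm, formula, total = compute_intakes(diary)

print(f"24 h milk production : {mp:6.1f} mL/24 h")
print(f"breast-milk intake   : {bm:6.1f} mL/24 h")
print(f"formula intake       : {formula:6.1f} mL/24 h")
print(f"total infant intake  : {total:6.1f} mL/24 h")
print()
print("Production sums the breastfeed volumes after the anchor feed and")
print("rescales by 24/T (here T = 24.5 h); the formula bottle enters the")
print("intake ledger but never the production ledger.")
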