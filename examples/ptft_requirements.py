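"""Proportional tit-for-tat needs repetition AND across-group variance.

A 2x2 factorial over rounds (1 vs 20) and across-group variance in pTFT
frequency (identical 3+3 groups vs 5+1 / 1+5 groups) in an iterated
public-goods game (b=2.4, c=1).
"""

from mlsel import StrategyProfile, mean_payoff_by_strategy
from mlsel.games import ALWAYS_CHEAT, PTFT

HI = ((PTFT,) * 5 + (ALWAYS_CHEAT,), (PTFT,) + (ALWAYS_CHEAT,) * 5)
LO = ((PTFT,) * 3 + (ALWAYS_CHEAT,) * 3,) * 2

print(f"{'rounds':>7} {'variance':>9} {'pTFT':>8} {'cheat':>8}  winner")
for rounds in (1, 20):
    for name, groups in (("low", LO), ("high", HI)):
        prof = StrategyProfile(groups=groups, rounds=rounds, benefit=2.4, cost=1.0)
        m = mean_payoff_by_strategy(prof, replicates=200, seed=8)
        winner = PTFT if m[PTFT] > m[ALWAYS_CHEAT] else ALWAYS_CHEAT
        print(f"{rounds:>7} {name:>9} {m[PTFT]:>8.3f} {m[ALWAYS_CHEAT]:>8.3f}  {winner}")

print("\npTFT earns the higher mean payoff only with BOTH repeated")
print("interactions and high across-group variance - the two requirements")
print("of partner fidelity feedback.")
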