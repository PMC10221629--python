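"""Ship emergency-braking distance as a function of driver fatigue.

Couples the predicted fatigue score to the driver's reaction time
(t1 = 1 s + 0.5 s per fatigue point) and computes the three-stroke braking
distance for a 10,000-tonne ship at 20 km/h with 1 MW reverse power and a
30 s reversing phase. Only the reaction stroke S1 depends on the driver;
S2 and S3 are fixed by the ship, so the distance penalty of fatigue is
u * slope * FSS.
"""

from fatiguebrake import (
    BrakingScenario, KMH_TO_MS, ReactionTimeMap,
    fatigue_to_reaction_time, total_braking_distance,
)

u = 20.0 * KMH_TO_MS
rmap = ReactionTimeMap(t_base=1.0, slope=0.5, t_max=10.0)

print(f"ship: u={u:.2f} m/s, m=1.0e7 kg, R=1.0e4 N s/m, P=1.0e6 W, reversing 30 s")
print(f"{'FSS':>4} {'t1 (s)':>7} {'S1 (m)':>8} {'S2 (m)':>8} {'S3 (m)':>8} {'total (m)':>10}")
for fss in (0.0, 1.0, 2.0, 3.0, 4.0):
    t1 = fatigue_to_reaction_time(fss, rmap)
    sc = BrakingScenario(u=u, t1=t1, t2=t1 + 30.0, m=1.0e7, R=1.0e4, P=1.0e6)
    res = total_braking_distance(sc)
    print(f"{fss:4.1f} {t1:7.2f} {res.s1:8.1f} {res.s2:8.1f} {res.s3:8.1f} "
          f"{res.s_total:10.1f}")
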