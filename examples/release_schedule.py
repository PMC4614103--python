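"""Release-schedule arithmetic for a 35-residue chain at 2 ns/residue.

One residue leaves the tunnel per interval, N-terminus first: during the
first 2 ns only residue 1 is free, during the next 2 ns residues 1-2, and
the chain is completely released at 35 x 2 = 70 ns.
"""

from cotrafold import ReleaseSchedule, confined_residues, total_release_time

sched = ReleaseSchedule(interval=2.0, n_residues=35)

for t in (1.0, 3.0, 35.0, 69.0, 70.0):
    confined = confined_residues(sched, t)
    span = f"{min(confined)}..{max(confined)}" if confined else "none"
    print(f"t = {t:5.1f} ns: {len(confined):2d} residues confined ({span})")

print(f"total release time: {total_release_time(sched):.0f} ns")
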