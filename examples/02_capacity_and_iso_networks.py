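"""Representational capacity and the iso-capacity family.

A population of N neurons with A active encodes C(N, A) distinct patterns.
Many (N, A) pairs share nearly the same capacity: starting from the benchmark
(100, 50), the scan finds for each active count A the population size N whose
capacity comes closest, sweeping sparseness from 50% down to 1.3% at (nearly)
constant coding capacity.
"""

from sparsenergy import NetworkConfig, exact_capacity, iso_capacity_scan

benchmark = NetworkConfig(N=100, A=50)
cap = exact_capacity(benchmark)
print(f"benchmark C(100,50) = {float(cap.exact):.5g}  (log10 = {cap.log_value:.3f})\n")

print(" N     A    p      cap/cap_ref  within 5%")
for row in iso_capacity_scan(benchmark):
    print(
        f"{row.net.N:4d}  {row.net.A:3d}  {row.net.p:6.3f}   "
        f"{row.capacity.normalized:8.3f}   {row.within_tolerance}"
    )

# Every row is a network with (approximately) the benchmark's capacity; the
# A=45 row is the one sparseness where no integer N lands within 5% — the
# capacity jump from N to N+1 straddles the benchmark there.
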