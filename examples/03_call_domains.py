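"""Primary interaction domains and the transition zone between them.

Runs the full pipeline (simulate -> profile -> exact least-squares
segmentation -> domain call) for both viewpoints of the default locus and
compares the called structure to the planted truth. The transition zone is
the overlap between the two called domains.
"""

from fourc.pipeline import analyze_locus
from fourc.simulate import SyntheticLocusSpec

spec = SyntheticLocusSpec()
result = analyze_locus(spec, seed=1)

for name, dom in result.domains.items():
    planted = result.truth.domain_intervals[name]
    print(f"{name}: called {dom.interval} (mean {dom.mean_signal:,.0f} RPM, {dom.confidence})")
    print(f"      planted {planted}  "
          f"edge errors {dom.interval.start - planted.start:+d} / {dom.interval.end - planted.end:+d} bp")

tz = result.tz
print(f"transition zone: {tz.relation}, {tz.interval}, width {tz.width / 1000:.1f} kb "
      f"(planted {spec.tz.length / 1000:.0f} kb)")
print(f"inter-viewpoint domain Jaccard: {result.domains['vpA'].jaccard(result.domains['vpB']):.3f} "
      "(near zero: the two genes occupy distinct structural domains)")
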