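# sbfdetect

Automated cell detection and counting for **bright-field microscopy**,
built around the convergence-index filter family: the Convergence Index
(CI), the Sliding Band Filter (SBF) and its transformed variant (TSBF).

Counting host cells (e.g. *Sf9* insect cells for baculovirus expression
work) is done daily on a hemocytometer, and manual counts are slow and
observer-dependent. In bright field, an unstained cell appears as a dark
membrane **ring** on a mid-gray background with an interior close to
background intensity, so threshold- and blob-based detectors that expect
filled convex objects fail. The TSBF turns both edges of the membrane
ring — the gradient that converges toward the cytoplasm just inside it
and the one that diverges just outside it — into a single strong response
at the cell center.

## The filters

For a candidate center $(x, y)$, the convergence index over a support
region $R$ is the mean alignment of the image gradient with the direction
toward the center:

$$\mathrm{CI}(x,y) = \frac{1}{|R|} \sum_{p \in R} \cos\alpha(p),$$

where $\alpha(p)$ is the angle between the gradient at support pixel $p$
and the unit vector from $p$ toward $(x,y)$. The SBF restricts $R$ to a
band of width $B_w$ that slides along each of $N$ radial rays, with the
band center $r \in [R_{\min}, R_{\max}]$ chosen per ray to maximize the
band-average $\cos\alpha$; the response is the mean over rays of each
ray's best band. The TSBF replaces the signed cosine by

$$\omega \cdot |\cos\alpha(p)| \cdot \|\nabla I(p)\|,$$

so membrane convergence *and* divergence both reinforce the center
response, and the gradient-magnitude weight suppresses the contrast-free
background noise that the plain cosine amplifies. Cell centers are the
thresholded local maxima of the TSBF map under $(n{+}1)\times(n{+}1)$
non-maximum suppression, and counts feed the standard hemocytometer
density formula (1 count per 1 mm² × 0.1 mm square = 10⁴ cells/mL before
dilution). Accuracy is summarized as the relative count error at each
sampled density (ERT) and its mean over densities (TERT).

Defaults follow the study settings: $R_{\min}=8$, $R_{\max}=30$ px,
$N=32$ rays, $B_w=6$ px, $\omega=1$, NMS window side $2R_{\min}+1=17$.

## Worked example

Everything is testable without real data: the `synth` module renders
bright-field scenes (dark membrane annuli, optical blur, Gaussian noise,
optional uneven illumination) with recorded ground truth.

```
$ python examples/detect_synthetic_scene.py
planted cells : 15
detected cells: 15
matched within 8 px: 15 (false positives 0, misses 0)
count error: 0.0%
```

Every planted ring cell produced exactly one TSBF maximum inside the cell,
so the frame's count error is zero. `examples/filter_responses.py` shows
why the transformation matters on a single ring cell:

```
CI  : response at center +0.0356, mean on membrane -0.0368, map max +0.1055
SBF : response at center +0.9676, mean on membrane +0.5175, map max +0.9740
TSBF: response at center +0.0379, mean on membrane +0.0187, map max +0.0384
```

TSBF's map maximum coincides with the cell center and its scale carries
gradient-magnitude units, which is what keeps noise-only frames near zero
(the signed-cosine SBF saturates near 1 even on weak spurious gradients).
`examples/counting_protocol.py` walks through the chamber-density and
ERT/TERT arithmetic.

A thin CLI wraps the same library:

```
sbfdetect detect --input plate.tif --rmin 8 --rmax 30 --out results/
sbfdetect synth  --preset brightfield-benchmark --images 15 --seed 42 --out bench/
sbfdetect eval   --detections results/plate.detections.csv --truth bench/truth_manifest.csv --out eval/
sbfdetect bench  --images 15 --seed 42 --out bench/   # synth -> detect -> eval
```

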