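"""Triangular fuzzy numbers: arithmetic, membership and defuzzification.

Builds a few TFNs, applies the arithmetic rules used throughout the
package, and compares the two defuzzifiers (graded mean integration and
centroid).
"""

from zefmea import TFN, defuzzify_centroid, defuzzify_gmir

a = TFN(1, 2, 3)
b = TFN(4, 5, 6)

print("a + b          =", a + b)            # componentwise sum
print("b - a          =", b - a)            # interval-widening subtraction
print("a * b          =", a * b)            # componentwise product (nonnegative)
print("b / a          =", b / a)            # (l1/u2, m1/m2, u1/l2)
print("0.5 * b        =", b.scale(0.5))

print("membership of 1.5 in a:", a.membership(1.5))

# GMIR weights the mode 4x; centroid averages the three vertices. They agree
# exactly for symmetric TFNs and differ for skewed ones.
skewed = TFN(0.7, 1.0, 1.0)
print("gmir(skewed)    =", defuzzify_gmir(skewed))    # 0.95
print("centroid(skewed)=", round(defuzzify_centroid(skewed), 4))  # 0.9
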