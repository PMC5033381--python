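# Molar-rotation contributions [M]D (deg·cm²·dag⁻¹) per residue, methyl
# pyranoside convention.  The neutral-hexose entries are classical
# literature values ([α]D of the methyl glycoside × its molar mass / 100,
# Bates & Associates / Hudson compilations); the galacturonic-acid and
# 6-deoxy-talose entries are back-calculated from the additive
# hexasaccharide sums of the B. longum 35624 exopolysaccharide study so
# that the two 6dTal epimer variants reproduce the published pair of
# calculated rotations.  Enantiomers contribute with opposite sign.
# Override with your own table via RotationConstants.from_yaml(path).
- residue: Glc
  anomeric: alpha
  absolute: D
  molar_rotation: 308.6
  source: "methyl α-D-glucopyranoside, [α]D +158.9, M 194.18"
- residue: Glc
  anomeric: beta
  absolute: D
  molar_rotation: -66.4
  source: "methyl β-D-glucopyranoside, [α]D -34.2, M 194.18"
- residue: Gal
  anomeric: alpha
  absolute: D
  molar_rotation: 346.2
  source: "methyl α-D-galactopyranoside, [α]D +178.3, M 194.18"
- residue: Man
  anomeric: alpha
  absolute: D
  molar_rotation: 153.8
  source: "methyl α-D-mannopyranoside, [α]D +79.2, M 194.18 (approximate)"
- residue: Rha
  anomeric: alpha
  absolute: L
  molar_rotation: -111.4
  source: "methyl α-L-rhamnopyranoside, [α]D -62.5, M 178.18 (approximate)"
- residue: Fuc
  anomeric: alpha
  absolute: L
  molar_rotation: -378.5
  source: "methyl α-L-fucopyranoside, [α]D -212.4, M 178.18 (approximate)"
- residue: GalA
  anomeric: alpha
  absolute: D
  molar_rotation: 98.3
  source: "back-calculated from the published hexasaccharide [M]D sums"
- residue: 6dTal
  anomeric: alpha
  absolute: D
  molar_rotation: 188.6
  source: "back-calculated, half the published D/L hexasaccharide [M]D gap"
- residue: 6dTal
  anomeric: alpha
  absolute: L
  molar_rotation: -188.6
  source: "enantiomer of the α-D value"
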