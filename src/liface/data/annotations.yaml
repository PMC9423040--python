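# Annotation presets: residue name -> atom name -> moiety / H-bond role /
# electron count.  Edit or extend to match your force field's atom names.
#
# Conventions: the beta-galactose ring atoms carry a prime ('), the glycerol
# backbone atoms a double prime (''), the alpha ring (DGDG only) is unprimed.
# The glycerol backbone moiety includes the glycosidic O1' oxygen.  A heavy
# atom is a donor iff it lists bonded hydrogens; `acceptor: true` marks
# H-bond acceptors.  Electron counts default from the element if omitted.
molecules:
  # --- synthetic test lipid (head-group + CH3 proxy; see liface.synth) -----
  SLX:
    kind: lipid
    atoms:
      C2P:  {moiety: glycerol, element: C, electrons: 6}
      OG:   {moiety: glycerol, element: O, electrons: 8, acceptor: true}
      OA:   {moiety: alpha_ring, element: O, electrons: 8, acceptor: true, hydrogens: [HA]}
      HA:   {moiety: alpha_ring, element: H, electrons: 1}
      OB:   {moiety: beta_ring, element: O, electrons: 8, acceptor: true, hydrogens: [HB]}
      HB:   {moiety: beta_ring, element: H, electrons: 1}
      O4P:  {moiety: beta_ring, element: O, electrons: 8, acceptor: true}
      RA1:  {moiety: alpha_ring, element: C, electrons: 6}
      RA2:  {moiety: alpha_ring, element: C, electrons: 6}
      RA3:  {moiety: alpha_ring, element: C, electrons: 6}
      RA4:  {moiety: alpha_ring, element: C, electrons: 6}
      RB1:  {moiety: beta_ring, element: C, electrons: 6}
      RB2:  {moiety: beta_ring, element: C, electrons: 6}
      RB3:  {moiety: beta_ring, element: C, electrons: 6}
      RB4:  {moiety: beta_ring, element: C, electrons: 6}
      CM:   {moiety: chain, element: C, electrons: 9}   # terminal CH3 proxy (C + 3H)

  # --- TIP3P-style 3-site water -------------------------------------------
  SOL: &water
    kind: water
    atoms:
      OW:   {moiety: water, element: O, electrons: 8, acceptor: true, hydrogens: [HW1, HW2]}
      HW1:  {moiety: water, element: H, electrons: 1}
      HW2:  {moiety: water, element: H, electrons: 1}
  TIP3: *water
  WAT: *water

  # --- MGDG: beta-galactosyl head on a diacylglycerol ----------------------
  # Template following the standard numbering; adapt atom names to your
  # topology.  Four ring hydroxyls (donor+acceptor), ring O5', glycosidic
  # O1' and the four ester oxygens are acceptor-only.
  MGDG:
    kind: lipid
    atoms:
      "C1''": {moiety: glycerol, element: C}
      "C2''": {moiety: glycerol, element: C}
      "C3''": {moiety: glycerol, element: C}
      "O1'":  {moiety: glycerol, element: O, acceptor: true}
      "C1'":  {moiety: beta_ring, element: C}
      "C2'":  {moiety: beta_ring, element: C}
      "C3'":  {moiety: beta_ring, element: C}
      "C4'":  {moiety: beta_ring, element: C}
      "C5'":  {moiety: beta_ring, element: C}
      "C6'":  {moiety: beta_ring, element: C}
      "O5'":  {moiety: beta_ring, element: O, acceptor: true}
      "O2'":  {moiety: beta_ring, element: O, acceptor: true, hydrogens: ["HO2'"]}
      "O3'":  {moiety: beta_ring, element: O, acceptor: true, hydrogens: ["HO3'"]}
      "O4'":  {moiety: beta_ring, element: O, acceptor: true, hydrogens: ["HO4'"]}
      "O6'":  {moiety: beta_ring, element: O, acceptor: true, hydrogens: ["HO6'"]}
      "HO2'": {moiety: beta_ring, element: H}
      "HO3'": {moiety: beta_ring, element: H}
      "HO4'": {moiety: beta_ring, element: H}
      "HO6'": {moiety: beta_ring, element: H}
      O11:    {moiety: chain, element: O, acceptor: true}
      O12:    {moiety: chain, element: O, acceptor: true}
      O21:    {moiety: chain, element: O, acceptor: true}
      O22:    {moiety: chain, element: O, acceptor: true}

  # --- DGDG: alpha(1->6)beta-digalactosyl head -----------------------------
  # The alpha ring (unprimed) replaces the beta-ring O6' hydroxyl hydrogen;
  # O6' becomes the glycosidic oxygen (acceptor-only).
  DGDG:
    kind: lipid
    atoms:
      "C1''": {moiety: glycerol, element: C}
      "C2''": {moiety: glycerol, element: C}
      "C3''": {moiety: glycerol, element: C}
      "O1'":  {moiety: glycerol, element: O, acceptor: true}
      "C1'":  {moiety: beta_ring, element: C}
      "C2'":  {moiety: beta_ring, element: C}
      "C3'":  {moiety: beta_ring, element: C}
      "C4'":  {moiety: beta_ring, element: C}
      "C5'":  {moiety: beta_ring, element: C}
      "C6'":  {moiety: beta_ring, element: C}
      "O5'":  {moiety: beta_ring, element: O, acceptor: true}
      "O2'":  {moiety: beta_ring, element: O, acceptor: true, hydrogens: ["HO2'"]}
      "O3'":  {moiety: beta_ring, element: O, acceptor: true, hydrogens: ["HO3'"]}
      "O4'":  {moiety: beta_ring, element: O, acceptor: true, hydrogens: ["HO4'"]}
      "O6'":  {moiety: beta_ring, element: O, acceptor: true}
      "HO2'": {moiety: beta_ring, element: H}
      "HO3'": {moiety: beta_ring, element: H}
      "HO4'": {moiety: beta_ring, element: H}
      C1:     {moiety: alpha_ring, element: C}
      C2:     {moiety: alpha_ring, element: C}
      C3:     {moiety: alpha_ring, element: C}
      C4:     {moiety: alpha_ring, element: C}
      C5:     {moiety: alpha_ring, element: C}
      C6:     {moiety: alpha_ring, element: C}
      O5:     {moiety: alpha_ring, element: O, acceptor: true}
      O2:     {moiety: alpha_ring, element: O, acceptor: true, hydrogens: [HO2]}
      O3:     {moiety: alpha_ring, element: O, acceptor: true, hydrogens: [HO3]}
      O4:     {moiety: alpha_ring, element: O, acceptor: true, hydrogens: [HO4]}
      O6:     {moiety: alpha_ring, element: O, acceptor: true, hydrogens: [HO6]}
      HO2:    {moiety: alpha_ring, element: H}
      HO3:    {moiety: alpha_ring, element: H}
      HO4:    {moiety: alpha_ring, element: H}
      HO6:    {moiety: alpha_ring, element: H}
      O11:    {moiety: chain, element: O, acceptor: true}
      O12:    {moiety: chain, element: O, acceptor: true}
      O21:    {moiety: chain, element: O, acceptor: true}
      O22:    {moiety: chain, element: O, acceptor: true}
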