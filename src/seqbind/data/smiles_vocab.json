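{
 "version": 1,
 "symbols": [
  "B",
  "C",
  "N",
  "O",
  "P",
  "S",
  "F",
  "I",
  "H",
  "Cl",
  "Br",
  "b",
  "c",
  "n",
  "o",
  "p",
  "s",
  "0",
  "1",
  "2",
  "3",
  "4",
  "5",
  "6",
  "7",
  "8",
  "9",
  "(",
  ")",
  "[",
  "]",
  "=",
  "#",
  "-",
  "+",
  "/",
  "\\",
  "@",
  "@@",
  ".",
  ":",
  "~",
  "*",
  "%10",
  "%11",
  "%12",
  "%13",
  "%14",
  "%15",
  "%16",
  "%17",
  "%18",
  "%19",
  "Si",
  "Se",
  "Na",
  "Li",
  "K",
  "Mg",
  "Ca",
  "Fe",
  "Zn",
  "Cu",
  "Mn",
  "Co",
  "Ni",
  "As",
  "Al",
  "Ag",
  "Au",
  "Pt",
  "Hg",
  "Pb",
  "Sn",
  "Sr",
  "Cr",
  "Cd",
  "Ti",
  "Ba",
  "<unk>"
 ]
}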