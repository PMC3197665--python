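>sp|P09172|DOPO_HUMAN Dopamine beta-hydroxylase precursor (617 aa)
MERGAARKSLPGPSMREAAFMYSTAVAIFLVILVAALQGSAPAESPFPFHIPLDPEGSLE
LSWNVSYTQEAIHFQLLVRRLKAGVLFGMSDRGELENADLVVLWTDGDTAYFADAWSDQK
GQIHLDPQQDYQLLQVQRTPEGLTLLFKRPFGTCDPNDYLIEDGTVHLVYGILEEPFRSL
EAINGSGLQMGLQRVQLLKPNIPEPELPSDACTMEVQAPNIQIPSQETTYWCYIKELPKG
FSRHHIIKYEPIVTKGNEALVHHMEVFQCAPEMDSVPHFSGPCDSKMKPDRLNYCRHVLA
AWALGAKAFYYPEEAGLAFGGPGSSRYLRLEVHYHNPLVIEGRNDSSGIRLYYTAKLRRF
NAGIMELGLVYTPVMAIPPRETAFILTGYCTDKCTQLALPPSGIHIFASQLHTHLTGRKV
VTVLVRDGREWEIVNQDNHYSPHFQEIRMLKKVVSVHPGDVLITSCTYNTEDRELATVGG
FGILEQMCVNYVHYYPQTQLELCKSAVDAGFLQKYFHLINRFNNEDVCTCPQASVSQQFT
SVPWNSFNRDVLKALYSFAPISMHCNKSSAVRFQGEWNLQPLPKVISTLEEPTPQCPTSQ
GRSPAGPTVVSIGGGKG
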