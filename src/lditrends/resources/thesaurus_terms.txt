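# Uninformative terms excluded from VOSviewer term maps: month and
# country names. Editable; one term per line.
january
february
march
april
may
june
july
august
september
october
november
december
afghanistan
argentina
australia
austria
bangladesh
belgium
brazil
bulgaria
canada
chile
china
colombia
croatia
cuba
czech republic
denmark
egypt
estonia
ethiopia
finland
france
germany
ghana
greece
hungary
iceland
india
indonesia
iran
iraq
ireland
israel
italy
japan
jordan
kenya
korea
latvia
lithuania
luxembourg
malaysia
mexico
morocco
nepal
netherlands
new zealand
nigeria
norway
pakistan
peru
philippines
poland
portugal
romania
russia
saudi arabia
serbia
singapore
slovakia
slovenia
south africa
spain
sweden
switzerland
taiwan
tanzania
thailand
tunisia
turkey
uganda
ukraine
united kingdom
united states
uruguay
venezuela
vietnam
zimbabwe
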