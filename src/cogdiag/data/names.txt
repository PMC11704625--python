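Sloan
Avery
Morgan
Riley
Quinn
Harper
Rowan
Sawyer
Emerson
Finley
Hayden
Peyton
Reese
Skyler
Tatum
Blake
Cameron
Dakota
Ellis
Frankie
Gray
Hollis
Jamie
Kendall
Lane
Marlow
Noel
Oakley
Parker
Remy
Shea
Teagan
Val
Winter
Adrian
Bailey
Casey
Devon
Eden
Flynn
Georgia
Henry
Iris
Jonah
Kara
Liam
Mara
Nora
Oscar
Petra
Quincy
Ruth
Simon
Thea
Ursula
Victor
Wendy
Xavier
Yara
Zane
Alice
Bernard
Clara
Douglas
Edith
Frank
Grace
Harold
Irene
James
Katherine
Louis
Margaret
Norman
Olive
Paul
Queenie
Robert
Sylvia
Thomas
Una
Vernon
Willa
Xenia
Yusuf
Zelda
Arthur
Beatrice
Carl
Dorothy
Ernest
Florence
George
Hazel
Isaac
June
Kenneth
Lillian
Martin
Nancy
Otto
Pearl
Quentin
Rosa
Stanley
Tessa
Ulric
Violet
Walter
Xiomara
Yvonne
Zachary
Ada
Benjamin
Celia
Dexter
Elsa
Felix
Gwen
Hugo
Ida
Jasper
Kira
Leon
Mona
Nils
Opal
Pablo
Queena
Rufus
Stella
Tobias
Uma
Vince
Wanda
Xander
Yolanda
Zeke
Amos
Bridget
Cyrus
Daphne
Eli
Fiona
Gideon
Hattie
Ivan
Josie
Kurt
Lena
Milo
Nadia
Orin
Phoebe
Quill
Rhea
Seth
Tilda
Upton
Vera
Wade
Ximena
York
Zara
Abel
Bonnie
Cedric
Dina
Edgar
Faye
Gus
Helena
Ira
Jules
Kyra
Lowell
Mabel
Ned
Odette
Pierce
Queen
Rory
Saul
Trudy
Ulla
Vito
Winnie
Xerxes
Yael
Zia
Alba
Boris
Cleo
Dmitri
Esme
Fritz
Greta
Hiram
Inga
Joel
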